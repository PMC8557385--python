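"""Log-log linear mixed models of mixing effects on growth and density.

Each model regresses a log-transformed circle metric on log-transformed
size/density covariates plus the mono/mixed dummy m, with a random
intercept per tree to absorb the correlation of repeated observations of
the same tree.  The de-logarithmized dummy coefficient e^a directly
gives the multiplicative mixing effect: a = 0.25 means mixed circles
exceed mono-specific ones by e^0.25 = 1.284, i.e. +28.4 %.

Model catalogue (response ~ fixed effects; all models add the per-tree
random intercept):

==== ========== =============================================
id   response   fixed terms
==== ========== =============================================
4.1  ln IMc     ln dqc, m, ln dqc x m
4.2  ln IMc     ln dqc, m
5    ln id      ln dqc, m
6    ln LAIc    ln dqc, ln dq, m
7    ln IMc     ln LAIc, m
8    ln id      ln d, ln SDIci, m        (main effects)
8i   ln id      ln d, ln SDIci x m       (interaction variant)
9    ln id      ln SDIc, m
10   ln IMc     ln SDIc, m
==== ========== =============================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec", "ModelFit", "MixingEffectEstimate", "MODEL_SPECS",
    "DegenerateDesignError", "build_model_table", "fit_lmm",
    "mixing_effect_percent", "effect_at_reference", "bootstrap_bands",
    "mixing_effect_from_fit",
]


class DegenerateDesignError(ValueError):
    """Raised when a fixed effect (e.g. the mixing dummy) is not estimable."""


@dataclass(frozen=True)
class ModelSpec:
    """One model of the catalogue: response and ordered fixed-effect terms.

    Term names: ``ln_*`` columns are log transforms of feature columns,
    ``m`` is the dummy and ``ln_x:m`` an interaction.
    """

    model_id: str
    response: str            # feature column, modelled on the ln scale
    terms: tuple[str, ...]   # fixed effects, in reporting order

    @property
    def log_columns(self) -> tuple[str, ...]:
        """Feature columns that must be strictly positive for this model."""
        cols = {self.response}
        for t in self.terms:
            for part in t.split(":"):
                if part.startswith("ln_"):
                    cols.add(part[3:])
        return tuple(sorted(cols))


MODEL_SPECS: dict[str, ModelSpec] = {
    "4.1": ModelSpec("4.1", "IMc", ("ln_dqc", "m", "ln_dqc:m")),
    "4.2": ModelSpec("4.2", "IMc", ("ln_dqc", "m")),
    "5": ModelSpec("5", "id", ("ln_dqc", "m")),
    "6": ModelSpec("6", "LAIc", ("ln_dqc", "ln_dq", "m")),
    "7": ModelSpec("7", "IMc", ("ln_LAIc", "m")),
    "8": ModelSpec("8", "id", ("ln_d", "ln_SDIci", "m")),
    "8i": ModelSpec("8i", "id", ("ln_d", "ln_SDIci:m")),
    "9": ModelSpec("9", "id", ("ln_SDIc", "m")),
    "10": ModelSpec("10", "IMc", ("ln_SDIc", "m")),
}


@dataclass
class ModelFit:
    model_id: str
    n_obs: int
    fixed: list[tuple[str, float, float, float]]  # (term, est, se, p)
    tau2: float
    sigma2: float
    converged: bool
    method: str = "reml"  # "reml" or "ols" fallback
    n_dropped: int = 0

    def coef(self, term: str) -> float:
        for t, est, _, _ in self.fixed:
            if t == term:
                return est
        raise KeyError(f"term {term!r} not in model {self.model_id}")

    def se(self, term: str) -> float:
        for t, _, se, _ in self.fixed:
            if t == term:
                return se
        raise KeyError(f"term {term!r} not in model {self.model_id}")


@dataclass
class MixingEffectEstimate:
    model_id: str
    group: str
    coefficient: float
    multiplier: float
    percent: float
    ci_low: float | None = None   # percent scale
    ci_high: float | None = None


def build_model_table(features: pd.DataFrame, model_id: str,
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Regression table for one model: log transforms and row filtering.

    Rows with non-positive values in any log-transformed column of this
    model are dropped; the per-column drop counts are returned alongside.
    The mixing dummy being constant is reported under the ``"m_constant"``
    key (dummy not estimable) rather than raising, so callers can decide.
    """
    spec = MODEL_SPECS[model_id]
    counts: dict[str, int] = {}
    keep = pd.Series(True, index=features.index)
    for col in spec.log_columns:
        ok = features[col] > 0
        counts[col] = int((~ok & keep).sum())
        keep &= ok
    sub = features[keep]
    if sub.empty:
        raise ValueError(f"model {model_id}: no rows left after filtering")
    table = pd.DataFrame(index=sub.index)
    table[f"ln_{spec.response}"] = np.log(sub[spec.response].to_numpy(float))
    for t in spec.terms:
        table[t] = _term_values(sub, t)
    table["m"] = sub["m"].to_numpy(int)
    table["tree_id"] = sub["tree_id"].to_numpy()
    counts["m_constant"] = int(sub["m"].nunique() <= 1)
    return table.reset_index(drop=True), counts


def _term_values(sub: pd.DataFrame, term: str) -> np.ndarray:
    vals = np.ones(len(sub))
    for part in term.split(":"):
        if part.startswith("ln_"):
            vals = vals * np.log(sub[part[3:]].to_numpy(float))
        elif part == "m":
            vals = vals * sub["m"].to_numpy(float)
        else:
            vals = vals * sub[part].to_numpy(float)
    return vals


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of the fixed effects with a per-tree random intercept.

    Falls back to OLS (flagged in ``method``) when no tree has repeated
    observations, in which case tau2 is reported as 0.  p-values use the
    large-sample normal approximation.
    """
    resp = f"ln_{spec.response}"
    y = table[resp].to_numpy(float)
    X = np.column_stack([np.ones(len(table))]
                        + [table[t].to_numpy(float) for t in spec.terms])
    names = ["intercept", *spec.terms]
    for j, t in enumerate(names):
        if j > 0 and np.ptp(X[:, j]) == 0:
            raise DegenerateDesignError(
                f"model {spec.model_id}: term {t!r} is constant "
                "(dummy not estimable)" if "m" in t else
                f"model {spec.model_id}: term {t!r} is constant")
    groups = pd.factorize(table["tree_id"])[0]
    repeated = np.bincount(groups).max() > 1

    if repeated:
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
        except np.linalg.LinAlgError:
            # gradient-based REML can hit a singular information matrix at
            # the tau2 = 0 boundary; retry derivative-free
            res = model.fit(reml=True, method="powell", maxiter=2000)
        if not res.converged:
            raise RuntimeError(
                f"model {spec.model_id}: mixed-model optimizer did not "
                f"converge ({res.mle_retvals if hasattr(res, 'mle_retvals') else 'no diagnostics'})")
        est = np.asarray(res.fe_params, float)
        se = np.asarray(res.bse_fe, float)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)
        method = "reml"
    else:
        res = sm.OLS(y, X).fit()
        est = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        tau2, sigma2 = 0.0, float(res.scale)
        method = "ols"
    from scipy import stats
    p = 2 * stats.norm.sf(np.abs(est / se))
    fixed = [(n, float(e), float(s), float(pv))
             for n, e, s, pv in zip(names, est, se, p)]
    return ModelFit(model_id=spec.model_id, n_obs=len(y), fixed=fixed,
                    tau2=tau2, sigma2=sigma2, converged=True, method=method)


def mixing_effect_percent(a_m: float) -> float:
    """Multiplicative mixing effect in percent: 100 (e^a - 1)."""
    if not math.isfinite(a_m):
        raise ValueError("coefficient must be finite")
    return 100.0 * (math.exp(a_m) - 1.0)


def mixing_effect_from_fit(fit: ModelFit, group: str = "",
                           m_term: str = "m") -> MixingEffectEstimate:
    a = fit.coef(m_term)
    s = fit.se(m_term)
    return MixingEffectEstimate(
        model_id=fit.model_id, group=group, coefficient=a,
        multiplier=math.exp(a), percent=mixing_effect_percent(a),
        ci_low=mixing_effect_percent(a - 1.96 * s),
        ci_high=mixing_effect_percent(a + 1.96 * s),
    )


def effect_at_reference(a_m: float, a_interaction: float,
                        dq_ref: float) -> float:
    """Mixed/mono ratio at a reference development stage dq_ref (cm).

    For models with an m x ln(dqc) interaction the multiplicative effect
    depends on the stand development stage: ratio = exp(a_m + a_int ln dq).
    """
    if dq_ref <= 0:
        raise ValueError("reference diameter must be positive")
    return math.exp(a_m + a_interaction * math.log(dq_ref))


def bootstrap_bands(fit: ModelFit, table: pd.DataFrame, spec: ModelSpec,
                    prediction_grid: pd.DataFrame, B: int, seed: int,
                    level: float = 0.95) -> pd.DataFrame:
    """Parametric-bootstrap percentile bands for model predictions.

    Simulates new responses from the fitted fixed effects plus freshly
    drawn tree effects b ~ N(0, tau2) and noise eps ~ N(0, sigma2),
    refits, and predicts on ``prediction_grid`` (one column per term,
    on the transformed scale).  Deterministic given ``seed``; aborts when
    more than 10 % of the refits fail.
    """
    if B < 50:
        raise ValueError("need B >= 50 bootstrap replicates")
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(len(table))]
                        + [table[t].to_numpy(float) for t in spec.terms])
    G = np.column_stack([np.ones(len(prediction_grid))]
                        + [prediction_grid[t].to_numpy(float) for t in spec.terms])
    beta = np.array([e for _, e, _, _ in fit.fixed])
    groups = pd.factorize(table["tree_id"])[0]
    n_groups = groups.max() + 1
    mu = X @ beta
    preds = np.empty((B, len(prediction_grid)))
    failures = 0
    work = table.copy()
    resp = f"ln_{spec.response}"
    for b in range(B):
        u = rng.normal(0.0, math.sqrt(max(fit.tau2, 0.0)), n_groups)
        eps = rng.normal(0.0, math.sqrt(fit.sigma2), len(table))
        work[resp] = mu + u[groups] + eps
        try:
            refit = fit_lmm(work, spec)
            bb = np.array([e for _, e, _, _ in refit.fixed])
            preds[b] = G @ bb
        except Exception:
            failures += 1
            preds[b] = np.nan
    if failures > 0.10 * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap refits failed (> 10 % tolerated)")
    alpha = (1.0 - level) / 2.0
    lo = np.nanquantile(preds, alpha, axis=0)
    hi = np.nanquantile(preds, 1.0 - alpha, axis=0)
    out = prediction_grid.copy()
    out["lo"] = lo
    out["hi"] = hi
    return out
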