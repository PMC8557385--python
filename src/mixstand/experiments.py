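"""Canned simulation experiments: parameter recovery and null calibration.

These define the package's standard validation conditions: even-aged
two-species stands of ~1600 trees on a 160 x 160 m plot, three surveys at
5-year steps, patch-wise mixing (25-30 m patches give a workable balance
of mono-specific and mixed circles), a tree-level random effect of
tau = 0.2 and residual noise sigma = 0.1 on the log-increment scale.
A replicate simulates the stand, computes circle features for both
periods, and fits the growth model matched to the generator
(ln id ~ ln d + ln SDIci + m, random intercept per tree), whose dummy
coefficient estimates the injected mixing effect beta.
"""

from __future__ import annotations

import pandas as pd

from .allometry import default_species_params
from .mixed_models import MODEL_SPECS, ModelFit, build_model_table, fit_lmm
from .neighborhood import circle_features
from .records import PlotDefinition
from .synthetic import GrowthLaw, SimulationConfig, simulate_stand

__all__ = ["recovery_config", "recovery_replicate", "recovery_study"]


def recovery_config(seed: int, beta: float = 0.20, *, n_trees: int = 1600,
                    tree_sd: float = 0.2, resid_sd: float = 0.1,
                    ages: tuple[float, ...] = (50.0, 55.0, 60.0),
                    ) -> SimulationConfig:
    plot = PlotDefinition("recovery", 160.0, 160.0, ages, ("spruce", "beech"))
    return SimulationConfig(
        plot=plot, n_trees=n_trees, pattern="grid_jitter",
        mixing_layout="patches", patch_size=30.0,
        growth_law=GrowthLaw(beta=beta),
        tree_sd=tree_sd, resid_sd=resid_sd, seed=seed,
    )


def recovery_replicate(seed: int, beta: float = 0.20, **kw) -> ModelFit:
    """One simulate-measure-fit replicate; returns the fitted growth model."""
    config = recovery_config(seed, beta, **kw)
    params = default_species_params()
    frame = simulate_stand(config, params)
    n_periods = len(config.plot.survey_ages) - 1
    feats = pd.concat(
        [circle_features(frame, config.plot, k, params,
                         mixed_threshold=config.mixed_threshold)
         for k in range(n_periods)],
        ignore_index=True)
    table, _ = build_model_table(feats, "8")
    return fit_lmm(table, MODEL_SPECS["8"])


def recovery_study(seeds, beta: float = 0.20, **kw) -> pd.DataFrame:
    """Replicated recovery: one row (seed, estimate, se) per seed."""
    rows = []
    for s in seeds:
        fit = recovery_replicate(int(s), beta, **kw)
        rows.append((int(s), fit.coef("m"), fit.se("m")))
    return pd.DataFrame(rows, columns=["seed", "beta_hat", "se"])
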