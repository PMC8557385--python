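"""Fit the mixed-model suite and extract multiplicative mixing effects.

Fits models 5, 8, 9 and 10 (random intercept per tree, REML) on the
feature table and writes a coefficient table plus the back-transformed
mixing-effect percents.  With the default simulation (injected
beta = 0.20 on log increment) the model-8 dummy should recover ~0.20,
i.e. a mixing effect of ~+22 %.
"""

import argparse
from pathlib import Path

import pandas as pd

from mixstand.mixed_models import (
    MODEL_SPECS,
    build_model_table,
    fit_lmm,
    mixing_effect_from_fit,
)

ap = argparse.ArgumentParser()
ap.add_argument("--features", type=Path, default=Path("results/features.tsv"))
ap.add_argument("--models", nargs="+", default=["5", "8", "9", "10"])
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

feats = pd.read_csv(args.features, sep="\t")
coef_rows, eff_rows = [], []
for mid in args.models:
    table, counts = build_model_table(feats, mid)
    fit = fit_lmm(table, MODEL_SPECS[mid])
    for term, est, se, p in fit.fixed:
        coef_rows.append((mid, term, est, se, p, fit.n_obs,
                          fit.tau2, fit.sigma2, fit.method))
    e = mixing_effect_from_fit(fit)
    eff_rows.append((mid, e.coefficient, e.multiplier, e.percent,
                     round(e.percent), e.ci_low, e.ci_high))
    print(f"model {mid}: n={fit.n_obs} dropped={sum(counts.values())} "
          f"m={e.coefficient:+.4f} -> {e.percent:+.1f}% "
          f"[{e.ci_low:+.1f}, {e.ci_high:+.1f}]")

args.out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(coef_rows, columns=[
    "model", "term", "estimate", "se", "p", "n_obs", "tau2", "sigma2",
    "method"]).to_csv(args.out / "model_coefficients.tsv", sep="\t",
                      index=False, float_format="%.6f")
pd.DataFrame(eff_rows, columns=[
    "model", "m_coefficient", "multiplier", "percent", "percent_rounded",
    "ci_low_pct", "ci_high_pct"]).to_csv(
        args.out / "mixing_effects.tsv", sep="\t", index=False,
        float_format="%.6f")
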