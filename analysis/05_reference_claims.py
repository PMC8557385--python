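"""Back-transform arithmetic on the bundled reference coefficient table.

Recomputes, from the shipped model-coefficient fixture, the multiplicative
mixing-effect percents of every model row, the development-stage ratios
for the interaction models (at dq = 20 and 40 cm), and the density-matched
trade-off ratios of all six species mixtures.  Nothing is refitted.
"""

import argparse
from pathlib import Path

import pandas as pd

from mixstand.reference import (
    GROUPS,
    load_reference_table,
    reference_effect_at_dq,
    reference_mixing_effects,
    reference_tradeoff,
    reference_tradeoff_ratio,
)

ap = argparse.ArgumentParser()
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

table = load_reference_table()
eff = reference_mixing_effects(table)
args.out.mkdir(parents=True, exist_ok=True)
eff.to_csv(args.out / "reference_mixing_effects.tsv", sep="\t",
           index=False, float_format="%.6f")

print("mixing-effect percents by model and mixture:")
print(eff[["equation", "group", "m_coefficient", "percent_rounded"]]
      .to_string(index=False))

rows = []
for key in GROUPS:
    p = reference_tradeoff(key, table)
    rows.append((key, p.K, p.gamma, p.delta,
                 reference_tradeoff_ratio(key, table)))
trade = pd.DataFrame(rows, columns=["group", "K", "gamma", "delta",
                                    "density_matched_ratio"])
trade.to_csv(args.out / "reference_tradeoff.tsv", sep="\t", index=False,
             float_format="%.6f")
print("\ndensity-matched trade-off ratios (mixed/mono at equal id):")
print(trade[["group", "gamma", "density_matched_ratio"]]
      .to_string(index=False))

print("\ninteraction-model ratios at dq = 20 / 40 cm:")
for key in ("spruce_beech", "oak_beech"):
    r20 = reference_effect_at_dq("4.1", key, 20.0, table)
    r40 = reference_effect_at_dq("4.1", key, 40.0, table)
    print(f"  {key}: {r20:.3f} / {r40:.3f}")
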