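"""Bundled reference coefficient table and its back-transform arithmetic.

The package ships the published fixed-effect coefficient table of the
model suite (models 4.1-10 for six Central European species mixtures) as
a TSV fixture.  It is used to verify the back-transform and elimination
arithmetic (multiplicative mixing effects, development-stage ratios,
trade-off curves) against the printed claims -- never refit, since the
underlying plot data are not deposited.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .mixed_models import effect_at_reference, mixing_effect_percent
from .tradeoff import TradeoffParams, density_matched_ratio, derive_tradeoff

__all__ = [
    "load_reference_table", "m_coefficient", "reference_mixing_effects",
    "reference_tradeoff", "GROUPS",
]

#: canonical group labels -> the table's printed group strings, per equation
GROUPS = {
    "spruce_beech": "N. sp., E. be.",
    "spruce_fir_beech": "N. sp., s. fir, E. be.",
    "spruce_pine": "N. sp., S. pi.",
    "pine_beech": "S. pi., E. be.",
    "oak_beech": "S. oak, E. be.",
    "ash_maple": "E. ash, syc. map.",
}


def load_reference_table() -> pd.DataFrame:
    """The bundled coefficient fixture as a DataFrame (p-values as strings)."""
    with resources.files("mixstand.data").joinpath("table5.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"equation": str})
    for c in ("a0", "a1", "a2", "a3", "sd_a0", "sd_a1", "sd_a2", "sd_a3"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def m_coefficient(row: pd.Series) -> float:
    """The mixing-dummy coefficient of one table row.

    In models 4.1, 4.2, 5, 7, 9 and 10 the dummy is the second covariate
    (a2; in 4.1 the a3 slot holds the m x ln(dqc) interaction).  In models
    6 and 8 the dummy is a3 where four coefficients are reported; a
    model-6 row reporting only three coefficients carries the dummy in a2
    (reduced term set for that species group).
    """
    eq = row["equation"]
    if eq in ("4.1", "4.2", "5", "7", "9", "10"):
        return float(row["a2"])
    if eq in ("6", "8"):
        a3 = row["a3"]
        if pd.isna(a3):
            return float(row["a2"])
        return float(a3)
    raise KeyError(f"unknown equation {eq!r}")


def reference_row(df: pd.DataFrame, equation: str, group_key: str) -> pd.Series:
    """First table row for one equation and canonical group key."""
    return _row(df, equation, group_key)


def _row(df: pd.DataFrame, equation: str, group_key: str) -> pd.Series:
    label = GROUPS[group_key]
    # printed group strings vary in trailing punctuation/capitalization
    norm = df["group"].str.lower().str.replace(".", "", regex=False).str.strip()
    target = label.lower().replace(".", "").strip()
    sel = df[(df["equation"] == equation) & (norm == target)]
    if sel.empty:
        raise KeyError(f"no row for equation {equation}, group {group_key}")
    return sel.iloc[0]


def reference_mixing_effects(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percent mixing effect for every row of the reference table."""
    if df is None:
        df = load_reference_table()
    out = df[["equation", "group", "variables", "n"]].copy()
    coefs = df.apply(m_coefficient, axis=1)
    out["m_coefficient"] = coefs
    out["multiplier"] = coefs.map(math.exp)
    out["percent"] = coefs.map(mixing_effect_percent)
    out["percent_rounded"] = out["percent"].round().astype(int)
    return out


def reference_effect_percent(equation: str, group_key: str,
                             df: pd.DataFrame | None = None) -> float:
    """Exact percent mixing effect of one published model row."""
    if df is None:
        df = load_reference_table()
    return mixing_effect_percent(m_coefficient(_row(df, equation, group_key)))


def reference_effect_at_dq(equation: str, group_key: str, dq_ref: float,
                           df: pd.DataFrame | None = None) -> float:
    """Mixed/mono ratio at dq_ref for a row with an m x ln(dqc) interaction."""
    if df is None:
        df = load_reference_table()
    row = _row(df, equation, group_key)
    if pd.isna(row["a3"]):
        raise ValueError(f"equation {equation} row has no interaction term")
    return effect_at_reference(float(row["a2"]), float(row["a3"]), dq_ref)


def reference_tradeoff(group_key: str,
                       df: pd.DataFrame | None = None) -> TradeoffParams:
    """Trade-off curve parameters from the published Model 9/10 rows."""
    if df is None:
        df = load_reference_table()
    r9 = _row(df, "9", group_key)
    r10 = _row(df, "10", group_key)
    return derive_tradeoff(
        (float(r9["a0"]), float(r9["a1"]), float(r9["a2"])),
        (float(r10["a0"]), float(r10["a1"]), float(r10["a2"])),
    )


def reference_tradeoff_ratio(group_key: str,
                             df: pd.DataFrame | None = None) -> float:
    """Density-matched mixed/mono productivity ratio e^delta for one group."""
    return density_matched_ratio(reference_tradeoff(group_key, df))
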