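"""Whole-plot per-survey summary characteristics.

Quadratic mean diameter, standing merchantable volume, leaf area index,
above-ground carbon stock, and the periodic annual volume increment IV.
Removal trees are credited in IV at the end of the period in which they
were removed, so thinning does not depress the growth bookkeeping.
Volume uses a configurable form factor; the 7 cm merchantability
threshold zeroes small trees' volume but not their leaf area or carbon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .allometry import (
    SpeciesParams,
    carbon_from_mass,
    predict_height,
    predict_leaf_area,
    predict_mass,
    resolve_species,
    stem_volume,
)
from .records import PlotDefinition

__all__ = ["StandSummary", "summarize_stand", "summary_table"]


@dataclass
class StandSummary:
    plot_id: str
    survey_index: int
    age: float
    n_live: int
    dq: float       # cm
    V: float        # m3/ha
    LAI: float      # m2/m2
    C: float        # Mg/ha
    IV: float | None  # m3/ha/yr; None without a successor survey


def _per_tree(stand: pd.DataFrame,
              species_params: Mapping[str, SpeciesParams]):
    sp = stand["species"].to_numpy()
    d = stand["d_cm"].to_numpy(float)
    age = stand["age_yr"].to_numpy(float)
    h = stand["h_m"].to_numpy(float) if "h_m" in stand else np.full(len(stand), np.nan)
    h = np.where(np.isfinite(h), h, np.nan)
    v = np.empty_like(d)
    la = np.empty_like(d)
    ma = np.empty_like(d)
    for s in np.unique(sp):
        p = resolve_species(s, species_params)
        sel = sp == s
        hs = h[sel]
        miss = ~np.isfinite(hs)
        if miss.any():
            hs = hs.copy()
            hs[miss] = predict_height(p.height_coefs, d[sel][miss], age[sel][miss])
        v[sel] = stem_volume(d[sel], hs, p.form_factor)
        la[sel] = predict_leaf_area(p.leaf_coefs, p.cf_leaf, d[sel])
        ma[sel] = predict_mass(p.mass_coefs, p.cf_mass, d[sel])
    return v, la, ma


def summarize_stand(tree_frame: pd.DataFrame, plot: PlotDefinition,
                    survey_index: int,
                    species_params: Mapping[str, SpeciesParams],
                    ) -> StandSummary:
    """Stand summary at one survey; IV uses the successor survey if present."""
    cur = tree_frame[tree_frame["survey_index"] == survey_index]
    if cur.empty:
        raise ValueError(f"no records at survey {survey_index}")
    live = cur[cur["status"] == "live"]
    area_ha = plot.area_ha
    age = float(cur["age_yr"].iloc[0])
    if live.empty:
        warnings.warn(f"survey {survey_index}: zero live trees", stacklevel=2)
        return StandSummary(plot.plot_id, survey_index, age, 0,
                            0.0, 0.0, 0.0, 0.0, None)
    v, la, ma = _per_tree(live, species_params)
    dq = math.sqrt(float(np.mean(live["d_cm"].to_numpy(float) ** 2)))
    V = float(np.sum(v)) / area_ha
    LAI = float(np.sum(la)) / plot.area_m2
    C = carbon_from_mass(float(np.sum(ma))) / 1000.0 / area_ha  # kg -> Mg/ha

    IV = None
    nxt = tree_frame[tree_frame["survey_index"] == survey_index + 1]
    if not nxt.empty:
        period = float(nxt["age_yr"].iloc[0]) - age
        live_n, removed_n = nxt[nxt["status"] == "live"], nxt[nxt["status"] == "removed"]
        # only removals that were still live at the period start are credited
        removed_n = removed_n[removed_n["tree_id"].isin(live["tree_id"])]
        v_end = float(np.sum(_per_tree(live_n, species_params)[0])) / area_ha if not live_n.empty else 0.0
        v_rem = float(np.sum(_per_tree(removed_n, species_params)[0])) / area_ha if not removed_n.empty else 0.0
        IV = (v_end + v_rem - V) / period
    return StandSummary(plot.plot_id, survey_index, age, len(live),
                        dq, V, LAI, C, IV)


def summary_table(tree_frame: pd.DataFrame, plot: PlotDefinition,
                  species_params: Mapping[str, SpeciesParams]) -> pd.DataFrame:
    """Per-survey summary rows for one plot."""
    rows = []
    for k in sorted(tree_frame["survey_index"].unique()):
        s = summarize_stand(tree_frame, plot, int(k), species_params)
        rows.append((s.plot_id, s.survey_index, s.age, s.n_live,
                     s.dq, s.V, s.LAI, s.C, s.IV))
    return pd.DataFrame(rows, columns=[
        "plot_id", "survey_index", "age_yr", "n_live",
        "dq_cm", "V_m3_ha", "LAI", "C_Mg_ha", "IV_m3_ha_yr"])
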