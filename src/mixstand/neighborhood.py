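"""Tree-centred sample circles and local density metrics.

Around every tree a circle of radius sr = 0.25 * h is constructed.  Edge
bias is removed by a toroidal shift of the rectangular plot (periodic
boundary; equivalent to searching all eight shifted copies).  On each
circle we compute the local Reineke stand density index with
(``SDIc``) and without (``SDIci``) the centre tree, the species-wise
equivalence-standardized mixing proportions, the quadratic mean diameter
``dqc``, leaf area index ``LAIc``, above-ground mass growth ``IMc`` and
the centre tree's annual diameter increment ``id``.  A circle is "mixed"
(m = 1) when the admixture of other species reaches the threshold
(default 10 %) of the standardized density.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .allometry import (
    MERCHANTABLE_MIN_D_CM,
    SpeciesParams,
    predict_height,
    predict_leaf_area,
    predict_mass,
    resolve_species,
)
from .records import PlotDefinition

__all__ = [
    "search_radius",
    "toroidal_distance_matrix",
    "toroidal_neighbors",
    "local_sdi",
    "species_local_sdi",
    "mixing_proportions",
    "classify_mixed",
    "annual_diameter_increment",
    "circle_features",
    "FEATURE_COLUMNS",
]

SDI_INDEX_DIAMETER_CM = 25.0

FEATURE_COLUMNS = [
    "plot_id", "tree_id", "species", "period_index", "age_start",
    "d", "h", "sr", "circle_area", "n_neighbors",
    "SDIci", "SDIc", "dqc", "LAIc", "IMc", "id",
    "admixture", "m", "dq",
]


def search_radius(h_center: float) -> float:
    """Neighbourhood search radius: a quarter of the centre tree's height."""
    if h_center <= 0:
        raise ValueError("height must be positive")
    return 0.25 * h_center


def _check_sr(plot: PlotDefinition, sr: float) -> None:
    if sr >= min(plot.width, plot.height) / 2.0:
        raise ValueError(
            f"search radius {sr:.2f} m >= half the shorter plot side "
            f"({min(plot.width, plot.height) / 2:.2f} m): a circle would "
            "overlap its own periodic image"
        )


def toroidal_distance_matrix(plot: PlotDefinition, x: np.ndarray,
                             y: np.ndarray) -> np.ndarray:
    """All pairwise distances under the periodic (toroidal) boundary.

    Uses the minimum-image convention over the 3 x 3 tiling of the plot,
    which is exact for separations below half the shorter plot side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    dx = np.minimum(dx, plot.width - dx)
    dy = np.minimum(dy, plot.height - dy)
    return np.hypot(dx, dy)


def toroidal_neighbors(plot: PlotDefinition, center_xy: tuple[float, float],
                       x: np.ndarray, y: np.ndarray, sr: float,
                       exclude: int | None = None) -> np.ndarray:
    """Indices of trees within ``sr`` of the centre under the toroidal shift.

    Membership is half-open: distance < sr is inside, distance == sr is
    outside.  ``exclude`` drops the centre tree's own index.
    """
    _check_sr(plot, sr)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.abs(x - center_xy[0])
    dy = np.abs(y - center_xy[1])
    dx = np.minimum(dx, plot.width - dx)
    dy = np.minimum(dy, plot.height - dy)
    dist = np.hypot(dx, dy)
    mask = dist < sr
    if exclude is not None:
        mask[exclude] = False
    return np.flatnonzero(mask)


def _weighted_alpha(d: np.ndarray, alphas: np.ndarray) -> float:
    """Basal-area-weighted mean self-thinning exponent of a circle."""
    w = d ** 2
    return float(np.sum(w * alphas) / np.sum(w))


def local_sdi(d: np.ndarray, species: np.ndarray, circle_area_m2: float,
              alpha_by_species: Mapping[str, float]) -> float:
    """Local stand density index (trees/ha at index diameter 25 cm).

    N = 10000/a * n is the per-hectare stem count on the circle, dq the
    quadratic mean diameter; SDI = N * (dq/25)^(-alpha) with alpha the
    basal-area-weighted mean of the species' self-thinning exponents
    (alpha < 0, so the exponent is the classical +1.605 at -1.605).
    An empty circle has SDI = 0.
    """
    if circle_area_m2 <= 0:
        raise ValueError("circle area must be positive")
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        return 0.0
    if np.any(d <= 0):
        raise ValueError("all diameters must be positive")
    alphas = np.array([alpha_by_species[s] for s in np.asarray(species)])
    n = d.size
    N = 10_000.0 / circle_area_m2 * n
    dq = math.sqrt(float(np.mean(d ** 2)))
    abar = _weighted_alpha(d, alphas)
    return N * (dq / SDI_INDEX_DIAMETER_CM) ** (-abar)


def species_local_sdi(d: np.ndarray, species: np.ndarray,
                      circle_area_m2: float,
                      alpha_by_species: Mapping[str, float]) -> dict[str, float]:
    """Species-wise local SDI values on one circle."""
    d = np.asarray(d, dtype=float)
    species = np.asarray(species)
    out: dict[str, float] = {}
    for s in np.unique(species):
        sel = species == s
        out[str(s)] = local_sdi(d[sel], species[sel], circle_area_m2,
                                alpha_by_species)
    return out


def mixing_proportions(d: np.ndarray, species: np.ndarray,
                       circle_area_m2: float,
                       equivalence_by_species: Mapping[str, float],
                       alpha_by_species: Mapping[str, float]) -> dict[str, float]:
    """Area-true species proportions of the standardized local density.

    Each species' local SDI is scaled by its density-equivalence factor
    before normalization, so species with larger growing-space demand are
    not under-represented.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("mixing proportions need a non-empty circle")
    sdis = species_local_sdi(d, species, circle_area_m2, alpha_by_species)
    weighted = {s: equivalence_by_species[s] * v for s, v in sdis.items()}
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("all equivalent densities are zero")
    return {s: v / total for s, v in weighted.items()}


def classify_mixed(mixport: Mapping[str, float], threshold: float = 0.10) -> int:
    """m = 1 when the admixture (1 - dominant share) reaches the threshold."""
    if not mixport:
        raise ValueError("empty mixing proportions")
    admixture = 1.0 - max(mixport.values())
    # tolerance keeps the >= boundary decision stable under float rounding
    return int(admixture >= threshold - 1e-12)


def annual_diameter_increment(d_start: float, d_end: float,
                              period: float) -> float:
    """Annual stem diameter increment in mm/yr from a survey period in years."""
    if period <= 0:
        raise ValueError("period length must be positive")
    return 10.0 * (d_end - d_start) / period


def circle_features(tree_frame: pd.DataFrame, plot: PlotDefinition,
                    period: int,
                    species_params: Mapping[str, SpeciesParams],
                    mixed_threshold: float = 0.10,
                    include_removed: bool = False) -> pd.DataFrame:
    """One row of circle metrics per centre tree for one survey period.

    Diameters are taken at the period start; circle membership is restricted
    to the remaining stand, i.e. trees surviving to the period end, unless
    ``include_removed`` is set.  Mass growth ``IMc`` (Mg/ha/yr) sums the
    dry-mass increment of circle trees with d >= 7 cm at the period start,
    leaf area index ``LAIc`` uses all circle trees, and the increment ``id``
    (mm/yr) belongs to the centre tree.  Negative or zero increments are
    retained here and filtered when model tables are built.
    """
    start = tree_frame[tree_frame["survey_index"] == period]
    end = tree_frame[tree_frame["survey_index"] == period + 1]
    if start.empty or end.empty:
        raise ValueError(
            f"need surveys {period} and {period + 1} for period features"
        )
    merged = start.merge(
        end[["tree_id", "d_cm", "status", "age_yr"]],
        on="tree_id", suffixes=("", "_end"),
    )
    live_start = merged[merged["status"] == "live"]
    if include_removed:
        stand = live_start
    else:
        stand = live_start[live_start["status_end"] == "live"]
    stand = stand.reset_index(drop=True)
    if stand.empty:
        raise ValueError("no surviving trees in the period")
    period_len = float(stand["age_yr_end"].iloc[0] - stand["age_yr"].iloc[0])
    if period_len <= 0:
        raise ValueError("survey ages must increase between surveys")

    sp = stand["species"].to_numpy()
    params = {s: resolve_species(s, species_params) for s in np.unique(sp)}
    alpha = {s: p.alpha for s, p in params.items()}
    equiv = {s: p.equivalence_factor for s, p in params.items()}

    d0 = stand["d_cm"].to_numpy(dtype=float)
    d1 = stand["d_cm_end"].to_numpy(dtype=float)
    age0 = stand["age_yr"].to_numpy(dtype=float)
    x = stand["x_m"].to_numpy(dtype=float)
    y = stand["y_m"].to_numpy(dtype=float)

    # centre-tree height: measured if present, else allometric imputation
    h = stand["h_m"].to_numpy(dtype=float) if "h_m" in stand else np.full(len(stand), np.nan)
    impute = ~np.isfinite(h)
    if impute.any():
        h = h.copy()
        for s in np.unique(sp[impute]):
            sel = impute & (sp == s)
            h[sel] = predict_height(params[s].height_coefs, d0[sel], age0[sel])

    ma0 = np.empty_like(d0)
    ma1 = np.empty_like(d0)
    la0 = np.empty_like(d0)
    for s in np.unique(sp):
        sel = sp == s
        p = params[s]
        ma0[sel] = predict_mass(p.mass_coefs, p.cf_mass, d0[sel])
        ma1[sel] = predict_mass(p.mass_coefs, p.cf_mass, d1[sel])
        la0[sel] = predict_leaf_area(p.leaf_coefs, p.cf_leaf, d0[sel])
    dmass = (ma1 - ma0) / period_len  # kg / yr per tree

    dist = toroidal_distance_matrix(plot, x, y)
    dq_stand = math.sqrt(float(np.mean(d0 ** 2)))

    rows = []
    for i in range(len(stand)):
        sr = search_radius(h[i])
        _check_sr(plot, sr)
        area = math.pi * sr ** 2
        inside = dist[i] < sr  # half-open: boundary excluded
        inside[i] = True  # centre always on its own circle
        neigh = inside.copy()
        neigh[i] = False

        sdici = local_sdi(d0[neigh], sp[neigh], area, alpha)
        sdic = local_sdi(d0[inside], sp[inside], area, alpha)
        dqc = math.sqrt(float(np.mean(d0[inside] ** 2)))
        laic = float(np.sum(la0[inside])) / area
        big = inside & (d0 >= MERCHANTABLE_MIN_D_CM)
        imc = float(np.sum(dmass[big])) * 10.0 / area  # kg/yr/m2 -> Mg/ha/yr
        mixport = mixing_proportions(d0[inside], sp[inside], area, equiv, alpha)
        m = classify_mixed(mixport, mixed_threshold)
        idv = annual_diameter_increment(d0[i], d1[i], period_len)

        rows.append((
            stand["plot_id"].iloc[i], stand["tree_id"].iloc[i], sp[i],
            period, age0[i], d0[i], h[i], sr, area, int(np.sum(neigh)),
            sdici, sdic, dqc, laic, imc, idv,
            1.0 - max(mixport.values()), m, dq_stand,
        ))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
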