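"""Synthetic spatial stand generator with known injected mixing effects.

Generates repeated-survey tree lists with the statistical structure the
downstream analysis assumes: even-aged rectangular plots, intimate or
patch-wise species mixing, lognormal initial diameters, a multiplicative
(log-scale) growth law with density and mixing effects, a tree-level
random intercept, i.i.d. log-scale noise, and optional thinning from
above.  Every downstream stage is thereby testable with a known truth.

Diameter increments are generated in mm/yr; the diameter advance
converts once, centrally, via d_next = d + id * period / 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .allometry import SpeciesParams, default_species_params, predict_height, resolve_species
from .neighborhood import (
    annual_diameter_increment,
    classify_mixed,
    local_sdi,
    mixing_proportions,
    search_radius,
    toroidal_distance_matrix,
    _check_sr,
)
from .records import PlotDefinition, TREE_COLUMNS

__all__ = ["GrowthLaw", "SimulationConfig", "generate_plot",
           "simulate_growth", "apply_thinning", "simulate_stand"]

#: increments are floored here (mm/yr) so diameters never shrink
MIN_INCREMENT_MM = 1e-3


@dataclass(frozen=True)
class GrowthLaw:
    """ln(id) = g0 + g1 ln d + g2 ln SDIci + beta m + b_tree + eps.

    ``id`` in mm/yr, ``d`` in cm, SDIci in trees/ha.  ``beta`` is the true
    multiplicative mixing effect on the log scale (beta = 0.25 means mixed
    trees grow e^0.25 = 1.284 times faster at matched size and density).
    """

    g0: float = 0.5
    g1: float = 0.8
    g2: float = -0.25
    beta: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    plot: PlotDefinition
    n_trees: int
    pattern: Literal["grid_jitter", "cluster"] = "grid_jitter"
    mixing_layout: Literal["intimate", "patches"] = "intimate"
    patch_size: float = 25.0
    target_species_shares: Mapping[str, float] = field(
        default_factory=lambda: {"spruce": 0.5, "beech": 0.5})
    initial_d_lognormal: tuple[float, float] = (3.0, 0.2)  # (meanlog, sdlog), cm
    growth_law: GrowthLaw = field(default_factory=GrowthLaw)
    tree_sd: float = 0.2      # s.d. tau of the per-tree random effect
    resid_sd: float = 0.1     # s.d. sigma of the per-observation noise
    thinning: tuple[int, float, str] | None = None  # (survey_index, fraction, rule)
    mixed_threshold: float = 0.10
    cluster_radius: float = 8.0
    cluster_size: int = 10
    jitter_frac: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        shares = dict(self.target_species_shares)
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError("species shares must sum to 1")
        if self.tree_sd < 0 or self.resid_sd < 0:
            raise ValueError("tau and sigma must be non-negative")
        if self.thinning is not None and not 0 <= self.thinning[1] < 1:
            raise ValueError("thinning fraction must be in [0, 1)")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        object.__setattr__(self, "target_species_shares", shares)


def _exact_counts(shares: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding of shares to integer counts summing to n."""
    keys = sorted(shares)
    raw = {k: shares[k] * n for k in keys}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def _positions(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    plot, n = config.plot, config.n_trees
    if config.pattern == "grid_jitter":
        # square planting grid filling the plot, uniform jitter, toroidal wrap
        nx = max(1, round(math.sqrt(n * plot.width / plot.height)))
        ny = max(1, math.ceil(n / nx))
        sx, sy = plot.width / nx, plot.height / ny
        gx, gy = np.meshgrid((np.arange(nx) + 0.5) * sx,
                             (np.arange(ny) + 0.5) * sy)
        x, y = gx.ravel()[:n].copy(), gy.ravel()[:n].copy()
        x += rng.uniform(-config.jitter_frac * sx, config.jitter_frac * sx, n)
        y += rng.uniform(-config.jitter_frac * sy, config.jitter_frac * sy, n)
    elif config.pattern == "cluster":
        # Matern-style parent-offspring process with exact total count
        n_parents = max(1, n // config.cluster_size)
        px = rng.uniform(0, plot.width, n_parents)
        py = rng.uniform(0, plot.height, n_parents)
        parent = rng.integers(0, n_parents, n)
        r = config.cluster_radius * np.sqrt(rng.uniform(0, 1, n))
        theta = rng.uniform(0, 2 * math.pi, n)
        x = px[parent] + r * np.cos(theta)
        y = py[parent] + r * np.sin(theta)
    else:
        raise ValueError(f"unknown pattern {config.pattern!r}")
    return x % plot.width, y % plot.height


def _assign_species(config: SimulationConfig, x: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    shares = config.target_species_shares
    n = len(x)
    if config.mixing_layout == "intimate":
        counts = _exact_counts(shares, n)
        pool = np.concatenate([np.full(c, s) for s, c in sorted(counts.items())])
        return pool[rng.permutation(n)]
    if config.mixing_layout == "patches":
        # square cells of patch_size; cells allotted to species by
        # largest-remainder on the cell count, in seeded random order
        ncx = max(1, math.ceil(config.plot.width / config.patch_size))
        ncy = max(1, math.ceil(config.plot.height / config.patch_size))
        cells = ncx * ncy
        cell_counts = _exact_counts(shares, cells)
        cell_species = np.concatenate(
            [np.full(c, s) for s, c in sorted(cell_counts.items())])
        cell_species = cell_species[rng.permutation(cells)]
        ix = np.minimum((x / config.patch_size).astype(int), ncx - 1)
        iy = np.minimum((y / config.patch_size).astype(int), ncy - 1)
        return cell_species[iy * ncx + ix]
    raise ValueError(f"unknown mixing layout {config.mixing_layout!r}")


def generate_plot(config: SimulationConfig,
                  species_params: Mapping[str, SpeciesParams] | None = None,
                  ) -> pd.DataFrame:
    """Survey-0 tree list (fixed TSV column layout) for the configured plot."""
    plot = config.plot  # validates geometry on construction
    rng = np.random.default_rng(config.seed)
    x, y = _positions(config, rng)
    species = _assign_species(config, x, y, rng)
    meanlog, sdlog = config.initial_d_lognormal
    d = rng.lognormal(meanlog, sdlog, config.n_trees)
    ids = [f"t{i:05d}" for i in range(config.n_trees)]
    age0 = plot.survey_ages[0]
    df = pd.DataFrame({
        "plot_id": plot.plot_id, "tree_id": ids, "species": species,
        "x_m": x, "y_m": y, "survey_index": 0, "age_yr": age0,
        "d_cm": d, "h_m": np.nan, "hcb_m": np.nan, "status": "live",
    })
    return df[TREE_COLUMNS]


def apply_thinning(frame: pd.DataFrame, survey_index: int, fraction: float,
                   rule: str = "from_above") -> pd.DataFrame:
    """Flag floor(n * fraction) trees as removed at ``survey_index``.

    ``from_above`` removes the largest-diameter live trees first; ties are
    broken deterministically by tree_id order.  Removed trees keep their
    records (status flag only) for all later surveys.
    """
    if not 0 <= fraction < 1:
        raise ValueError("thinning fraction must be in [0, 1)")
    if rule != "from_above":
        raise ValueError(f"unknown thinning rule {rule!r}")
    out = frame.copy()
    at = out[(out["survey_index"] == survey_index) & (out["status"] == "live")]
    k = int(math.floor(len(at) * fraction))
    if k == 0:
        return out
    ranked = at.sort_values(["d_cm", "tree_id"], ascending=[False, True])
    victims = set(ranked["tree_id"].iloc[:k])
    mask = out["tree_id"].isin(victims) & (out["survey_index"] >= survey_index)
    out.loc[mask, "status"] = "removed"
    return out


def _local_state(frame_period: pd.DataFrame, plot: PlotDefinition,
                 species_params: Mapping[str, SpeciesParams],
                 mixed_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree (SDIci, m) of the live stand at one survey."""
    live = frame_period[frame_period["status"] == "live"].reset_index(drop=True)
    sp = live["species"].to_numpy()
    params = {s: resolve_species(s, species_params) for s in np.unique(sp)}
    alpha = {s: p.alpha for s, p in params.items()}
    equiv = {s: p.equivalence_factor for s, p in params.items()}
    d = live["d_cm"].to_numpy(dtype=float)
    age = live["age_yr"].to_numpy(dtype=float)
    h = np.empty_like(d)
    for s in np.unique(sp):
        sel = sp == s
        h[sel] = predict_height(params[s].height_coefs, d[sel], age[sel])
    dist = toroidal_distance_matrix(
        plot, live["x_m"].to_numpy(float), live["y_m"].to_numpy(float))
    n = len(live)
    sdici = np.empty(n)
    m = np.empty(n, dtype=int)
    for i in range(n):
        sr = search_radius(h[i])
        _check_sr(plot, sr)
        area = math.pi * sr ** 2
        inside = dist[i] < sr
        inside[i] = True
        neigh = inside.copy()
        neigh[i] = False
        sdici[i] = local_sdi(d[neigh], sp[neigh], area, alpha)
        mixport = mixing_proportions(d[inside], sp[inside], area, equiv, alpha)
        m[i] = classify_mixed(mixport, mixed_threshold)
    return sdici, m


def simulate_growth(survey0: pd.DataFrame, config: SimulationConfig,
                    species_params: Mapping[str, SpeciesParams] | None = None,
                    ) -> pd.DataFrame:
    """Advance the survey-0 tree list through all configured surveys.

    For each period, ln(id) = g0 + g1 ln d + g2 ln SDIci + beta m + b + eps
    with the tree effect b ~ N(0, tau^2) drawn once per tree and
    eps ~ N(0, sigma^2) per observation; d advances by id * period / 10
    (id mm/yr, d cm) and increments are floored at a small positive value.
    Thinning, if configured, is applied at its survey before that period's
    densities are evaluated.
    """
    if survey0 is None or survey0.empty:
        raise ValueError("survey-0 records are required")
    params = species_params or default_species_params()
    plot = config.plot
    ages = plot.survey_ages
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    law = config.growth_law

    order = survey0["tree_id"].to_numpy()
    b_tree = dict(zip(order, rng.normal(0.0, config.tree_sd, len(order))))

    frame = survey0.copy()
    for k in range(len(ages) - 1):
        if config.thinning is not None and config.thinning[0] == k:
            frame = apply_thinning(frame, k, config.thinning[1], config.thinning[2])
        cur = frame[frame["survey_index"] == k].reset_index(drop=True)
        live = cur[cur["status"] == "live"].reset_index(drop=True)
        sdici, m = _local_state(cur, plot, params, config.mixed_threshold)
        period = ages[k + 1] - ages[k]
        eps = rng.normal(0.0, config.resid_sd, len(live))
        b = np.array([b_tree[t] for t in live["tree_id"]])
        log_id = (law.g0 + law.g1 * np.log(live["d_cm"].to_numpy(float))
                  + law.g2 * np.log(np.maximum(sdici, 1.0))
                  + law.beta * m + b + eps)
        idv = np.maximum(np.exp(log_id), MIN_INCREMENT_MM)

        nxt = cur.copy()
        nxt["survey_index"] = k + 1
        nxt["age_yr"] = ages[k + 1]
        live_ids = live["tree_id"].to_numpy()
        growth = dict(zip(live_ids, idv * period / 10.0))
        nxt["d_cm"] = [
            dc + growth.get(t, 0.0)
            for t, dc in zip(nxt["tree_id"], nxt["d_cm"])
        ]
        frame = pd.concat([frame, nxt], ignore_index=True)
    return frame.reset_index(drop=True)


def simulate_stand(config: SimulationConfig,
                   species_params: Mapping[str, SpeciesParams] | None = None,
                   ) -> pd.DataFrame:
    """Generate survey 0 and simulate growth through all surveys."""
    params = species_params or default_species_params()
    return simulate_growth(generate_plot(config, params), config, params)
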