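"""File formats and end-to-end experiment orchestration.

Tree lists travel as a fixed-column TSV with ``# key: value`` header
comment lines (plot geometry, survey ages, seed).  The experiment runner
chains the stages: (synthetic) tree lists -> per-period circle features
-> mixed-model fits -> multiplicative mixing effects -> trade-off curve
-> stand summaries, writing every artifact as TSV with the config and
seed embedded so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import SpeciesParams, default_species_params
from .mixed_models import (
    MODEL_SPECS,
    ModelFit,
    build_model_table,
    fit_lmm,
    mixing_effect_from_fit,
)
from .neighborhood import circle_features
from .records import PlotDefinition, TREE_COLUMNS
from .stand_summary import summary_table
from .synthetic import SimulationConfig, simulate_stand
from .tradeoff import TradeoffParams, density_matched_ratio, derive_tradeoff, evaluate_tradeoff

__all__ = ["RunConfig", "read_tree_list", "write_tree_list", "run_experiment"]

log = logging.getLogger("mixstand")

_NUMERIC = {"x_m", "y_m", "age_yr", "d_cm", "h_m", "hcb_m"}


def write_tree_list(frame: pd.DataFrame, path: str | Path,
                    plot: PlotDefinition, seed: int | None = None) -> None:
    """Write a tree-list TSV with plot geometry and seed in header comments."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# plot_id: {plot.plot_id}\n")
        fh.write(f"# width_m: {plot.width}\n")
        fh.write(f"# height_m: {plot.height}\n")
        fh.write(f"# survey_ages: {','.join(str(a) for a in plot.survey_ages)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="",
                     float_format="%.6f", lineterminator="\n")


def read_tree_list(path: str | Path) -> tuple[pd.DataFrame, PlotDefinition, dict[str, str]]:
    """Parse a tree-list TSV; strict about schema, decimal points and keys.

    Returns the table, the plot definition reconstructed from the header,
    and the raw header metadata.  Malformed rows (comma decimals, wrong
    field count, unknown status) are rejected with their line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    body_lines: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if line.strip() == "":
                continue
            body.append(line)
            body_lines.append(lineno)
    if not body:
        raise ValueError(f"{path}: no data rows")
    header = body[0].rstrip("\n").split("\t")
    if header != TREE_COLUMNS:
        raise ValueError(f"{path}: column header mismatch: {header}")
    rows = []
    for line, lineno in zip(body[1:], body_lines[1:]):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(TREE_COLUMNS):
            raise ValueError(f"{path} line {lineno}: expected "
                             f"{len(TREE_COLUMNS)} fields, got {len(fields)}")
        rec = dict(zip(TREE_COLUMNS, fields))
        for col in _NUMERIC:
            val = rec[col]
            if val == "":
                rec[col] = math.nan
                continue
            if "," in val:
                raise ValueError(
                    f"{path} line {lineno}: comma decimal in column "
                    f"{col!r} ({val!r}); the dialect requires decimal points")
            try:
                rec[col] = float(val)
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: bad numeric "
                                 f"{col!r} = {val!r}") from exc
        try:
            rec["survey_index"] = int(rec["survey_index"])
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: bad survey_index "
                             f"{rec['survey_index']!r}") from exc
        if rec["status"] not in ("live", "removed"):
            raise ValueError(f"{path} line {lineno}: unknown status token "
                             f"{rec['status']!r}")
        rows.append(rec)
    df = pd.DataFrame(rows, columns=TREE_COLUMNS)
    dup = df.duplicated(["plot_id", "tree_id", "survey_index"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (plot_id, tree_id, survey_index) "
                         f"keys at rows {list(df.index[dup])}")
    ages = tuple(float(a) for a in meta.get("survey_ages", "").split(",")) \
        if meta.get("survey_ages") else tuple(sorted(df["age_yr"].unique()))
    plot = PlotDefinition(
        plot_id=meta.get("plot_id", str(df["plot_id"].iloc[0])),
        width=float(meta["width_m"]), height=float(meta["height_m"]),
        survey_ages=ages,
    )
    return df, plot, meta


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment."""

    simulation: SimulationConfig
    out_dir: str | Path
    models: tuple[str, ...] = ("5", "8", "9", "10")
    mixed_threshold: float = 0.10
    dq_refs: tuple[float, float] = (20.0, 40.0)
    bootstrap_B: int = 0        # 0 disables bootstrap bands
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mixed_threshold < 0.5:
            raise ValueError("mixed threshold must be in (0, 0.5)")
        if any(r <= 0 for r in self.dq_refs):
            raise ValueError("reference diameters must be positive")


def _features_all_periods(frame: pd.DataFrame, plot: PlotDefinition,
                          params: Mapping[str, SpeciesParams],
                          threshold: float) -> pd.DataFrame:
    n_surveys = int(frame["survey_index"].max()) + 1
    parts = [
        circle_features(frame, plot, k, params, mixed_threshold=threshold)
        for k in range(n_surveys - 1)
    ]
    return pd.concat(parts, ignore_index=True)


def run_experiment(config: RunConfig,
                   species_params: Mapping[str, SpeciesParams] | None = None,
                   tree_frame: pd.DataFrame | None = None) -> dict:
    """Run the full analysis chain and write the report bundle.

    Uses the synthetic generator unless ``tree_frame`` provides real data.
    Returns a dict with the in-memory artifacts (features, fits, effects,
    trade-off parameters, summaries).  Every output table lands under
    ``config.out_dir``; the run is deterministic given config and seed.
    """
    params = species_params or default_species_params()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    plot = sim.plot

    log.info("stage=simulate seed=%d", sim.seed)
    if tree_frame is None:
        tree_frame = simulate_stand(sim, params)
    write_tree_list(tree_frame, out / "tree_list.tsv", plot, seed=sim.seed)

    log.info("stage=features threshold=%.2f", config.mixed_threshold)
    features = _features_all_periods(tree_frame, plot, params,
                                     config.mixed_threshold)
    features.to_csv(out / "features.tsv", sep="\t", index=False,
                    float_format="%.6f")
    n_nonpos = int((features["id"] <= 0).sum())
    log.info("stage=features rows=%d nonpositive_id=%d",
             len(features), n_nonpos)

    fits: dict[str, ModelFit] = {}
    effects = []
    for mid in config.models:
        table, counts = build_model_table(features, mid)
        log.info("stage=fit model=%s rows=%d dropped=%s", mid, len(table), counts)
        fit = fit_lmm(table, MODEL_SPECS[mid])
        fit.n_dropped = sum(v for k, v in counts.items() if k != "m_constant")
        fits[mid] = fit
        if "m" in MODEL_SPECS[mid].terms:
            effects.append(mixing_effect_from_fit(fit))

    eff_df = pd.DataFrame(
        [(e.model_id, e.coefficient, e.multiplier, e.percent,
          round(e.percent), e.ci_low, e.ci_high) for e in effects],
        columns=["model", "m_coefficient", "multiplier", "percent",
                 "percent_rounded", "ci_low_pct", "ci_high_pct"])
    eff_df.to_csv(out / "mixing_effects.tsv", sep="\t", index=False,
                  float_format="%.6f")

    trade: TradeoffParams | None = None
    if "9" in fits and "10" in fits:
        f9 = [fits["9"].coef(t) for t in ("intercept", "ln_SDIc", "m")]
        f10 = [fits["10"].coef(t) for t in ("intercept", "ln_SDIc", "m")]
        trade = derive_tradeoff(f9, f10)
        grid = np.linspace(0.5, 6.0, 23)
        curve = pd.DataFrame({
            "id_mm_yr": grid,
            "IMc_mono": evaluate_tradeoff(trade, grid, 0),
            "IMc_mixed": evaluate_tradeoff(trade, grid, 1),
        })
        curve["ratio"] = curve["IMc_mixed"] / curve["IMc_mono"]
        curve.to_csv(out / "tradeoff_curve.tsv", sep="\t", index=False,
                     float_format="%.6f")
        log.info("stage=tradeoff gamma=%.4f ratio=%.4f",
                 trade.gamma, density_matched_ratio(trade))

    summaries = summary_table(tree_frame, plot, params)
    summaries.to_csv(out / "stand_summary.tsv", sep="\t", index=False,
                     float_format="%.6f")

    manifest = {
        "seed": sim.seed,
        "n_trees": sim.n_trees,
        "models": list(config.models),
        "mixed_threshold": config.mixed_threshold,
        "n_feature_rows": int(len(features)),
        "n_nonpositive_id": n_nonpos,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "tree_frame": tree_frame, "features": features, "fits": fits,
        "effects": effects, "tradeoff": trade, "summaries": summaries,
    }
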