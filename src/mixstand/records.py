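"""Core record types: plot geometry and per-tree survey records."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["PlotDefinition", "TreeSurveyRecord", "records_to_frame", "frame_to_records"]

#: fixed column order of the tree-list table
TREE_COLUMNS = [
    "plot_id", "tree_id", "species", "x_m", "y_m",
    "survey_index", "age_yr", "d_cm", "h_m", "hcb_m", "status",
]


@dataclass(frozen=True)
class PlotDefinition:
    """Rectangular plot geometry and survey schedule.

    Coordinates are in metres with the origin at the lower-left corner;
    ``area_ha`` is derived.  Survey ages must be strictly increasing.
    """

    plot_id: str
    width: float
    height: float
    survey_ages: tuple[float, ...]
    species_pool: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"plot {self.plot_id!r}: width and height must be positive "
                f"(got {self.width} x {self.height}); non-rectangular or "
                "zero-area plots are not supported"
            )
        ages = tuple(float(a) for a in self.survey_ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("survey_ages must be strictly increasing")
        object.__setattr__(self, "survey_ages", ages)

    @property
    def area_ha(self) -> float:
        return self.width * self.height / 10_000.0

    @property
    def area_m2(self) -> float:
        return self.width * self.height


@dataclass
class TreeSurveyRecord:
    """One tree at one survey."""

    plot_id: str
    tree_id: str
    species: str
    x: float
    y: float
    survey_index: int
    age: float
    d: float
    h: float | None = None
    hcb: float | None = None
    status: str = "live"
    crown_radii: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status not in ("live", "removed"):
            raise ValueError(f"unknown status token {self.status!r}")
        if self.status == "live" and self.d <= 0:
            raise ValueError(
                f"tree {self.tree_id!r} survey {self.survey_index}: "
                "live records need d > 0"
            )


def records_to_frame(records: Iterable[TreeSurveyRecord]) -> pd.DataFrame:
    """Flatten records into the fixed-column tree-list table."""
    rows = [
        (r.plot_id, r.tree_id, r.species, r.x, r.y, r.survey_index,
         r.age, r.d, r.h, r.hcb, r.status)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=TREE_COLUMNS)
    df["survey_index"] = df["survey_index"].astype(int)
    return df


def frame_to_records(df: pd.DataFrame) -> list[TreeSurveyRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(TreeSurveyRecord(
            plot_id=str(row.plot_id), tree_id=str(row.tree_id),
            species=str(row.species), x=float(row.x_m), y=float(row.y_m),
            survey_index=int(row.survey_index), age=float(row.age_yr),
            d=float(row.d_cm),
            h=None if pd.isna(row.h_m) else float(row.h_m),
            hcb=None if pd.isna(row.hcb_m) else float(row.hcb_m),
            status=str(row.status),
        ))
    return recs
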