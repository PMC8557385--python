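"""Per-species auxiliary allometric models.

Tree height is modelled on stem diameter and age on the log-log scale,
above-ground dry mass and one-sided leaf area as power laws of diameter.
Back-transformed predictions from ln-scale regressions carry a
multiplicative correction factor CF = exp(s2/2) for the lognormal
retransformation bias (Baskerville-type).  Carbon is half of dry mass;
merchantable stem volume uses a cylindrical form factor with a 7 cm
small-end threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesParams",
    "HeightFit",
    "fit_height_model",
    "predict_height",
    "predict_mass",
    "predict_leaf_area",
    "bias_correction_factor",
    "carbon_from_mass",
    "stem_volume",
    "resolve_species",
    "default_species_params",
    "MERCHANTABLE_MIN_D_CM",
]

MERCHANTABLE_MIN_D_CM = 7.0

#: species codes treated as conifers when falling back to generalized parameters
CONIFER_CODES = frozenset({"spruce", "fir", "pine", "larch", "douglas", "conifer"})


@dataclass(frozen=True)
class SpeciesParams:
    """Allometric and density parameters for one species.

    ``alpha`` is the self-thinning exponent (negative by convention; the
    classical species-overarching value is -1.605).  ``equivalence_factor``
    standardizes stem-number density across species with different growing
    space requirements.  ``form_factor`` reduces the d-h cylinder to
    merchantable stem volume.
    """

    species: str
    height_coefs: tuple[float, float, float, float]
    mass_coefs: tuple[float, float]
    cf_mass: float
    leaf_coefs: tuple[float, float]
    cf_leaf: float
    alpha: float
    equivalence_factor: float
    form_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.cf_mass < 1.0 or self.cf_leaf < 1.0:
            raise ValueError("correction factors CF must be >= 1")
        if self.alpha >= 0:
            raise ValueError("self-thinning exponent alpha must be negative")
        if self.equivalence_factor <= 0:
            raise ValueError("equivalence_factor must be positive")
        if not 0 < self.form_factor <= 1:
            raise ValueError("form_factor must be in (0, 1]")


@dataclass
class HeightFit:
    """OLS fit of the log-log height model with diagnostics."""

    coefs: tuple[float, float, float, float]
    resid_var: float
    r2: float
    n: int
    downgraded: bool = False
    dropped_terms: tuple[str, ...] = field(default_factory=tuple)


def fit_height_model(samples: Sequence[tuple[float, float, float]]) -> HeightFit:
    """Fit ln(h) = a0 + a1 ln(d) + a2 ln(age) + a3 ln(d) ln(age) by OLS.

    ``samples`` is a sequence of (d_cm, age_yr, h_m) triples.  If the design
    is rank-deficient (e.g. a single age in an even-aged plot), the age and
    interaction terms are dropped and the downgrade is flagged on the result.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 5:
        raise ValueError("need >= 5 samples of (d, age, h)")
    if np.any(arr <= 0):
        raise ValueError("d, age and h must all be positive")
    ld, lage, lh = np.log(arr[:, 0]), np.log(arr[:, 1]), np.log(arr[:, 2])

    X_full = np.column_stack([np.ones_like(ld), ld, lage, ld * lage])
    dropped: tuple[str, ...] = ()
    X = X_full
    if np.linalg.matrix_rank(X_full) < 4:
        X = X_full[:, :2]
        dropped = ("ln_age", "ln_d:ln_age")
    beta, _, rank, _ = np.linalg.lstsq(X, lh, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("height design matrix is rank deficient even after downgrade")
    resid = lh - X @ beta
    dof = max(len(lh) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    ss_tot = float(np.sum((lh - lh.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
    coefs = tuple(beta) + (0.0,) * (4 - len(beta))
    return HeightFit(coefs=coefs, resid_var=s2, r2=r2, n=len(lh),
                     downgraded=bool(dropped), dropped_terms=dropped)


def predict_height(height_coefs: Sequence[float], d, age):
    """Height in m from the log-log model; accepts scalars or arrays."""
    a0, a1, a2, a3 = height_coefs
    d = np.asarray(d, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(d <= 0) or np.any(age <= 0):
        raise ValueError("d and age must be positive")
    ld, lage = np.log(d), np.log(age)
    out = np.exp(a0 + a1 * ld + a2 * lage + a3 * ld * lage)
    return float(out) if out.ndim == 0 else out


def predict_mass(mass_coefs: Sequence[float], cf_mass: float, d):
    """Above-ground dry mass in kg: exp(a0 + a1 ln d) * CFm."""
    a0, a1 = mass_coefs
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    out = np.exp(a0 + a1 * np.log(d)) * cf_mass
    return float(out) if out.ndim == 0 else out


def predict_leaf_area(leaf_coefs: Sequence[float], cf_leaf: float, d):
    """One-sided leaf area in m2: exp(a0 + a1 ln d) * CFla."""
    a0, a1 = leaf_coefs
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    out = np.exp(a0 + a1 * np.log(d)) * cf_leaf
    return float(out) if out.ndim == 0 else out


def bias_correction_factor(residual_variance_log: float) -> float:
    """CF = exp(s2/2) for back-transforming ln-scale predictions.

    With additive Gaussian noise on the ln scale, exp(fitted) estimates the
    median; multiplying by exp(s2/2) recovers the arithmetic mean.
    """
    if residual_variance_log < 0:
        raise ValueError("residual variance must be non-negative")
    return math.exp(residual_variance_log / 2.0)


def carbon_from_mass(ma):
    """Carbon content as 0.50 * above-ground dry mass (same units)."""
    ma = np.asarray(ma, dtype=float)
    if np.any(ma < 0):
        raise ValueError("mass must be non-negative")
    out = 0.5 * ma
    return float(out) if out.ndim == 0 else out


def stem_volume(d, h, form_factor: float):
    """Merchantable stem volume in m3: (pi/4)(d/100)^2 h f, zero below 7 cm."""
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("d and h must be positive")
    if not 0 < form_factor <= 1:
        raise ValueError("form_factor must be in (0, 1]")
    v = (math.pi / 4.0) * (d / 100.0) ** 2 * h * form_factor
    v = np.where(d < MERCHANTABLE_MIN_D_CM, 0.0, v)
    return float(v) if v.ndim == 0 else v


def resolve_species(species: str,
                    params: Mapping[str, SpeciesParams]) -> SpeciesParams:
    """Look up species parameters, falling back to the generalized set.

    Unknown codes resolve to the generalized ``conifer`` or ``broadleaf``
    parameter set (by a coarse code heuristic), never silently to another
    concrete species.
    """
    if species in params:
        return params[species]
    fallback = "conifer" if species.lower() in CONIFER_CODES else "broadleaf"
    if fallback in params:
        return params[fallback]
    raise KeyError(
        f"no parameters for species {species!r} and no generalized "
        f"{fallback!r} fallback present"
    )


def default_species_params() -> dict[str, SpeciesParams]:
    """Synthetic default parameter sets for the simulation experiments.

    These are plausibility-tuned placeholders for Central European conifer /
    broadleaf species (heights ~20 m at d=20 cm, ~300 kg dry mass at
    d=25 cm); real analyses must supply measured, species-specific values.
    """
    conifer = SpeciesParams(
        species="conifer",
        height_coefs=(1.14, 0.45, 0.13, 0.0),
        mass_coefs=(-2.0, 2.4), cf_mass=1.02,
        leaf_coefs=(-1.5, 1.9), cf_leaf=1.05,
        alpha=-1.664, equivalence_factor=1.0, form_factor=0.5,
    )
    broadleaf = SpeciesParams(
        species="broadleaf",
        height_coefs=(1.05, 0.47, 0.13, 0.0),
        mass_coefs=(-1.7, 2.35), cf_mass=1.02,
        leaf_coefs=(-1.8, 1.9), cf_leaf=1.04,
        alpha=-1.789, equivalence_factor=1.9, form_factor=0.5,
    )
    d = {
        "conifer": conifer,
        "broadleaf": broadleaf,
        "spruce": SpeciesParams(
            species="spruce",
            height_coefs=(1.14, 0.45, 0.13, 0.0),
            mass_coefs=(-2.0, 2.4), cf_mass=1.02,
            leaf_coefs=(-1.5, 1.9), cf_leaf=1.05,
            alpha=-1.664, equivalence_factor=1.0, form_factor=0.5,
        ),
        "beech": SpeciesParams(
            species="beech",
            height_coefs=(1.05, 0.47, 0.13, 0.0),
            mass_coefs=(-1.7, 2.35), cf_mass=1.02,
            leaf_coefs=(-1.8, 1.9), cf_leaf=1.04,
            alpha=-1.789, equivalence_factor=1.9, form_factor=0.5,
        ),
    }
    return d
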