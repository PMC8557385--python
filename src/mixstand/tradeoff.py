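"""Density-eliminated trade-off between stand mass growth and stem growth.

Models 9 and 10 regress ln(id) and ln(IMc) on ln(SDIc) and the mixing
dummy m.  Equalizing the two in ln(SDIc) eliminates density and yields
the closed-form curve

    IMc(id, m) = K * id^gamma * e^(delta m)

with gamma = b1/a1, K = exp(b0 - b1 a0/a1) and delta = b2 - b1 a2/a1,
where (a0, a1, a2) are the Model-9 and (b0, b1, b2) the Model-10
coefficients.  gamma < 0 reproduces the classical hyperbolic trade-off;
e^delta is the density-matched productivity ratio of mixed over
mono-specific stands at any given diameter increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TradeoffParams", "derive_tradeoff", "evaluate_tradeoff",
           "density_matched_ratio"]


@dataclass(frozen=True)
class TradeoffParams:
    K: float
    gamma: float
    delta: float
    source: tuple[str, str] = ("9", "10")


def derive_tradeoff(fit9: Sequence[float], fit10: Sequence[float],
                    ) -> TradeoffParams:
    """Eliminate ln(SDIc) between Models 9 and 10.

    ``fit9`` = (a0, a1, a2) of ln(id) = a0 + a1 ln SDIc + a2 m and
    ``fit10`` = (b0, b1, b2) of ln(IMc) = b0 + b1 ln SDIc + b2 m.
    Requires a1 != 0 (density-dependent diameter growth), otherwise the
    curve is undefined.
    """
    a0, a1, a2 = fit9
    b0, b1, b2 = fit10
    if a1 == 0:
        raise ValueError("Model 9 density coefficient a1 = 0: "
                         "diameter growth is density-independent and the "
                         "trade-off curve is undefined")
    gamma = b1 / a1
    K = math.exp(b0 - b1 * a0 / a1)
    delta = b2 - b1 * a2 / a1
    return TradeoffParams(K=K, gamma=gamma, delta=delta)


def evaluate_tradeoff(params: TradeoffParams, id_mm, m) -> np.ndarray | float:
    """IMc (Mg/ha/yr) on the curve at increment ``id_mm`` (mm/yr)."""
    id_arr = np.asarray(id_mm, dtype=float)
    if np.any(id_arr <= 0):
        raise ValueError("diameter increment must be positive")
    m_arr = np.asarray(m, dtype=float)
    out = params.K * id_arr ** params.gamma * np.exp(params.delta * m_arr)
    return float(out) if out.ndim == 0 else out


def density_matched_ratio(params: TradeoffParams) -> float:
    """Mixed/mono productivity ratio at matched diameter increment: e^delta."""
    return math.exp(params.delta)
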