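"""Distance-conditioned residual slice imputation.

Given two observed parallel slices x1, x2 and the distances d1, d2 from
the target location to each, the imputed slice is

    y_hat = y_lin + S(x1, x2, d1, d2),

where the linear baseline is the convex combination

    y_lin = (d2 / d) * x1 + (d1 / d) * x2,      d = d1 + d2,

and S is a 2D U-Net predicting the residual from a 4-channel input in
which d1 and d2 are replicated into constant planes.  Because the network
is trained on min-max-normalized intensities, the residual it outputs
lives on the unit intensity scale; at inference it is mapped back to the
raw scale of the bounding slices (see :func:`impute_slice`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import UNet

logger = logging.getLogger(__name__)


@dataclass
class ImputationQuery:
    """One imputation request: bounding slices and distances (mm) to each.

    ``x1`` is the anterior slice, ``x2`` the posterior one; ``d1`` and
    ``d2`` are the nonnegative distances from the target coordinate to x1
    and x2, so d1 + d2 is the slab thickness and must be positive.
    """

    x1: np.ndarray
    x2: np.ndarray
    d1: float
    d2: float

    def __post_init__(self):
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape or self.x1.ndim != 2:
            raise ValueError("x1 and x2 must be 2D slices of equal shape")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("distances must be nonnegative")
        if self.d1 + self.d2 == 0:
            raise ValueError("d1 + d2 must be positive")


def linear_interpolate(query: ImputationQuery) -> np.ndarray:
    """Distance-weighted linear interpolation of the two bounding slices.

    The weights form an exact convex combination: the closer slice gets
    the larger weight, and d1 = 0 returns x1 exactly.
    """
    d = query.d1 + query.d2
    if query.d1 == 0:
        return query.x1.copy()
    if query.d2 == 0:
        return query.x2.copy()
    return (query.d2 / d) * query.x1 + (query.d1 / d) * query.x2


def assemble_input(query: ImputationQuery) -> np.ndarray:
    """Stack (x1, x2, d1-plane, d2-plane) into the network's 4-channel input.

    The distance channels are constant planes holding d1 and d2 in mm
    (unnormalized).  Channel order is fixed as documented.
    """
    h, w = query.x1.shape
    out = np.empty((4, h, w))
    out[0] = query.x1
    out[1] = query.x2
    out[2] = query.d1
    out[3] = query.d2
    return out


def _pair_range(query: ImputationQuery) -> tuple[float, float]:
    lo = min(query.x1.min(), query.x2.min())
    hi = max(query.x1.max(), query.x2.max())
    return float(lo), float(hi)


def impute_slice(query: ImputationQuery, net: UNet, *,
                 clip: bool = True) -> np.ndarray:
    """Impute the slice at the query coordinate: y_hat = y_lin + residual.

    The network sees the two slices jointly min-max normalized by the
    range of the bounding pair (so the linear baseline stays a convex
    combination on the unit scale) and the raw distances in mm; its
    residual is scaled back by the pair's dynamic range and added to the
    raw-scale linear baseline.  With ``clip`` enabled, pixels that the
    residual pushes outside the pair's intensity range are clipped back
    (the linear baseline itself is never altered, which keeps the
    zero-residual network an exact linear interpolator).
    """
    y_lin = linear_interpolate(query)
    lo, hi = _pair_range(query)
    scale = hi - lo
    if scale > 0:
        norm_query = ImputationQuery((query.x1 - lo) / scale,
                                     (query.x2 - lo) / scale,
                                     query.d1, query.d2)
    else:
        norm_query = ImputationQuery(np.zeros_like(query.x1),
                                     np.zeros_like(query.x2),
                                     query.d1, query.d2)
    x = assemble_input(norm_query)[None]
    residual = np.asarray(net.forward(x)[0, 0], dtype=float)
    if scale == 0:
        return y_lin
    out = y_lin + scale * residual
    if clip:
        mask = residual != 0
        n_out = int(((out < lo) | (out > hi))[mask].sum())
        if n_out:
            logger.debug("impute_slice: clipped %d pixels to [%g, %g]",
                         n_out, lo, hi)
        out[mask] = np.clip(out[mask], lo, hi)
    return out


def predict_residual(query: ImputationQuery, net: UNet) -> np.ndarray:
    """The raw network residual on the normalized intensity scale."""
    lo, hi = _pair_range(query)
    scale = hi - lo
    if scale > 0:
        query = ImputationQuery((query.x1 - lo) / scale,
                                (query.x2 - lo) / scale,
                                query.d1, query.d2)
    x = assemble_input(query)[None]
    return np.asarray(net.forward(x)[0, 0], dtype=float)
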