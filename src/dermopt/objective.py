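"""The contrast-quality objective and its ingredients.

A candidate enhanced lightness channel ``ψe`` is scored by

    C(ψe) = log(log(ψs)) · edgels(ψe) · G(ψe) / (M · N)

where ``ψs`` is the summed Sobel gradient magnitude, ``edgels`` counts pixels
whose gradient magnitude exceeds a threshold (default: the mean magnitude),
and ``G`` is the Gini coefficient of the pixel intensities — a normalized
mean absolute pairwise difference measuring how unequally intensity is
distributed.  The double logarithm damps runaway contrast stretching.  Larger
``C`` means a sharper, more widely spread intensity distribution; the hybrid
enhancer maximizes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ObjectiveBreakdown",
    "count_edgels",
    "gini",
    "objective",
    "sobel_sum",
]

# standard 3x3 Sobel kernels; vertical detects horizontal gradients
_SOBEL_V = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_H = _SOBEL_V.T

# floor for the inner log argument so log(log(.)) stays defined
_LOG_GUARD = math.e + 1e-9


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Objective value ``cost`` together with its three factors."""

    cost: float
    sobel_sum: float
    edgel_count: int
    gini: float
    loglog_term: float


def sobel_sum(channel: np.ndarray) -> tuple[float, np.ndarray]:
    """Summed Sobel gradient magnitude and the per-pixel magnitude field."""
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2 or min(channel.shape) < 3:
        raise ValueError(
            f"need a 2-D channel of at least 3x3, got shape {channel.shape}"
        )
    gv = ndimage.convolve(channel, _SOBEL_V, mode="nearest")
    gh = ndimage.convolve(channel, _SOBEL_H, mode="nearest")
    magnitude = np.hypot(gv, gh)
    # kernel weights sum to zero; snap float residue on flat regions so a
    # constant image reports exactly zero energy and zero edgels
    magnitude[magnitude < 1e-12] = 0.0
    return float(magnitude.sum()), magnitude


def count_edgels(magnitude: np.ndarray, threshold: float | None = None) -> int:
    """Count pixels with gradient magnitude strictly above ``threshold``.

    With ``threshold=None`` the global mean of the magnitude field is used,
    a parameter-free rule under which the count is always < M·N.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if threshold is None:
        threshold = float(magnitude.mean())
    return int(np.count_nonzero(magnitude > threshold))


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a set of non-negative intensities.

    Equals ``Σ_j Σ_k |x_j − x_k| / (2 n² μ)``, evaluated through the
    O(n log n) sorted-order identity ``Σ_i (2i − n − 1) x_(i) / (n² μ)``.
    Returns 0 for an all-zero input (μ = 0) by convention.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("gini of an empty set is undefined")
    mu = x.mean()
    if mu <= 0.0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * n * mu))


def objective(
    channel: np.ndarray, edgel_threshold: float | None = None
) -> ObjectiveBreakdown:
    """Full objective breakdown for an enhanced lightness channel.

    The inner log argument is floored at ``e + 1e-9`` so the outer log is
    defined; a gradient-free channel has no edgels and scores exactly 0, so
    the guard only ever prevents NaN, never changes a meaningful score.
    """
    s, magnitude = sobel_sum(channel)
    edgels = count_edgels(magnitude, edgel_threshold)
    g = gini(channel)
    loglog = math.log(math.log(max(s, _LOG_GUARD)))
    n_pixels = channel.size
    cost = 0.0 if edgels == 0 else loglog * edgels * g / n_pixels
    return ObjectiveBreakdown(
        cost=cost,
        sobel_sum=s,
        edgel_count=edgels,
        gini=g,
        loglog_term=loglog,
    )
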