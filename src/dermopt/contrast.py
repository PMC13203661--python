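"""The four-parameter local-statistics contrast transformation.

Each pixel of the lightness channel is remapped by

    δg(x,y) = [Pδ · μg / (ψσ(x,y) + Pβ)] · (δf(x,y) − Pτ · ψμ(x,y)) + ψμ(x,y)^Pα

where ``ψμ``/``ψσ`` are windowed mean/std fields, ``μg`` the global mean, and
the result is clipped to ``[0, 1]``.  The gain term amplifies deviation from
the (weighted) local mean most strongly in flat regions; the ``ψμ^Pα`` offset
conserves local brightness.  The four parameters ``(Pα, Pβ, Pτ, Pδ)`` are the
optimizer's search space, box-bounded by ``PARAM_LOWER``/``PARAM_UPPER``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dermopt.image_core import LocalStatsField

__all__ = [
    "PARAM_LOWER",
    "PARAM_UPPER",
    "EnhancementParams",
    "apply_transform",
]

# search-box bounds, ordered (alpha, beta, tau, delta)
PARAM_LOWER = np.array([0.0, 0.0, 0.0, 0.5])
PARAM_UPPER = np.array([1.6, 0.5, 0.8, 1.5])


@dataclass(frozen=True)
class EnhancementParams:
    """The transformation parameters.

    alpha : exponent on the local mean (brightness-conservation offset)
    beta  : smoothing constant in the gain denominator
    tau   : weight of the local-mean subtraction
    delta : global gain factor
    """

    alpha: float
    beta: float
    tau: float
    delta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.tau, self.delta])

    @classmethod
    def from_array(cls, vec) -> "EnhancementParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (4,):
            raise ValueError(f"expected 4 parameters, got shape {vec.shape}")
        return cls(*(float(v) for v in vec))

    def validate_bounds(self) -> None:
        vec = self.as_array()
        if np.any(vec < PARAM_LOWER) or np.any(vec > PARAM_UPPER):
            raise ValueError(
                f"parameters {vec} outside bounds [{PARAM_LOWER}, {PARAM_UPPER}]"
            )


def apply_transform(
    channel: np.ndarray, stats: LocalStatsField, params: EnhancementParams
) -> np.ndarray:
    """Apply the transformation to a lightness channel; output in ``[0, 1]``.

    Where the gain denominator ``ψσ + Pβ`` is zero (a zero-variance window
    with ``Pβ = 0``) the gain term is treated as 0 at those pixels.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != stats.local_mean.shape:
        raise ValueError(
            f"channel shape {channel.shape} does not match stats "
            f"{stats.local_mean.shape}"
        )
    denom = stats.local_std + params.beta
    gain = np.zeros_like(channel)
    np.divide(params.delta * stats.global_mean, denom, out=gain, where=denom > 0)
    out = gain * (channel - params.tau * stats.local_mean)
    # 0^0 -> 1 under numpy power; local mean of an [0,1] image is >= 0
    out += stats.local_mean**params.alpha
    return np.clip(out, 0.0, 1.0)
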