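"""Image I/O, RGB↔HSL conversion, and local/global intensity statistics.

All images are held as float arrays with intensities in ``[0, 1]``; 8-bit
files are scaled by 255 on read and write.  Enhancement operates on the HSL
lightness channel only, so the conversions here use the bi-hexcone HSL model
(lightness ``L = (max + min) / 2``), not HSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LocalStatsField",
    "hsl_to_rgb",
    "load_image",
    "local_stats",
    "rgb_to_hsl",
    "save_image",
]


@dataclass(frozen=True)
class LocalStatsField:
    """Per-pixel neighbourhood statistics of a lightness channel.

    Attributes
    ----------
    local_mean : ndarray, shape (M, N)
        Mean over a ``window``×``window`` neighbourhood (replicate-padded).
    local_std : ndarray, shape (M, N)
        Population standard deviation over the same neighbourhood.
    global_mean : float
        Mean over the whole channel.
    window : int
        Odd window edge length.
    """

    local_mean: np.ndarray
    local_std: np.ndarray
    global_mean: float
    window: int


def _check_rgb(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB array, got shape {pixels.shape}")
    return pixels


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file as an H×W×3 float array in ``[0, 1]``."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def save_image(path, pixels: np.ndarray) -> None:
    """Write an ``[0, 1]`` float RGB array as an 8-bit image file."""
    pixels = _check_rgb(pixels)
    out = np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="RGB").save(path)


def rgb_to_hsl(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an RGB image in ``[0, 1]`` to (hue, saturation, lightness).

    Hue is in degrees ``[0, 360)``; saturation and lightness in ``[0, 1]``.
    Hue of achromatic pixels is 0 by convention.
    """
    pixels = _check_rgb(pixels)
    r, g, b = pixels[..., 0], pixels[..., 1], pixels[..., 2]
    cmax = pixels.max(axis=-1)
    cmin = pixels.min(axis=-1)
    delta = cmax - cmin
    light = (cmax + cmin) / 2.0

    sat = np.zeros_like(light)
    chromatic = delta > 0
    # s = delta / (1 - |2L - 1|) on chromatic pixels
    denom = 1.0 - np.abs(2.0 * light - 1.0)
    np.divide(delta, denom, out=sat, where=chromatic & (denom > 0))

    hue = np.zeros_like(light)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / delta, 6.0)
        hg = (b - r) / delta + 2.0
        hb = (r - g) / delta + 4.0
    hue = np.where(chromatic & (cmax == r), hr, hue)
    hue = np.where(chromatic & (cmax == g) & (cmax != r), hg, hue)
    hue = np.where(chromatic & (cmax == b) & (cmax != r) & (cmax != g), hb, hue)
    hue = np.where(chromatic, hue * 60.0, 0.0)
    return hue, np.clip(sat, 0.0, 1.0), light


def hsl_to_rgb(
    hue: np.ndarray, sat: np.ndarray, light: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsl`; returns an H×W×3 array in ``[0, 1]``."""
    hue = np.asarray(hue, dtype=float)
    sat = np.asarray(sat, dtype=float)
    light = np.asarray(light, dtype=float)
    if not (hue.shape == sat.shape == light.shape):
        raise ValueError(
            f"channel shapes differ: {hue.shape}, {sat.shape}, {light.shape}"
        )
    c = (1.0 - np.abs(2.0 * light - 1.0)) * sat
    hp = np.mod(hue, 360.0) / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    z = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r1 = np.select(
        [sector == 0, sector == 1, sector == 2, sector == 3, sector == 4],
        [c, x, z, z, x],
        default=c,
    )
    g1 = np.select(
        [sector == 0, sector == 1, sector == 2, sector == 3, sector == 4],
        [x, c, c, x, z],
        default=z,
    )
    b1 = np.select(
        [sector == 0, sector == 1, sector == 2, sector == 3, sector == 4],
        [z, z, x, c, c],
        default=x,
    )
    m = light - c / 2.0
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


def local_stats(channel: np.ndarray, window: int = 3) -> LocalStatsField:
    """Windowed mean/std and global mean of a lightness channel.

    The window is replicate-padded at the borders; the standard deviation is
    the population form (divide by the window pixel count).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {channel.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    mean = ndimage.uniform_filter(channel, size=window, mode="nearest")
    sq_mean = ndimage.uniform_filter(channel * channel, size=window, mode="nearest")
    var = np.clip(sq_mean - mean * mean, 0.0, None)
    # snap float-cancellation residue to an exact zero so constant windows
    # report zero spread (the transform's gain guard keys on sigma == 0)
    var[var < 1e-14] = 0.0
    return LocalStatsField(
        local_mean=mean,
        local_std=np.sqrt(var),
        global_mean=float(channel.mean()),
        window=window,
    )
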