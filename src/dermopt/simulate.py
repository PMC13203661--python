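"""Seeded synthetic inputs emulating the structure the pipeline assumes.

Three generators cover the pipeline's input types:

* :func:`gen_lesion_image` — a skin-toned textured background with a darker
  elliptical lesion (irregular boundary, optional hair strokes) and its
  ground-truth mask; the lesion/background lightness gap is controllable, so
  "low contrast" is a number, not an impression.
* :func:`gen_feature_matrix` — a labelled feature matrix with known
  informative, linearly redundant, and pure-noise columns, standing in for
  fused deep-feature matrices.
* :func:`gen_group_accuracies` — Gaussian per-group samples for exercising
  the ANOVA layer.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dermopt.fusion import FeatureMatrix
from dermopt.image_core import hsl_to_rgb

__all__ = [
    "FeatureFixture",
    "LesionFixture",
    "gen_feature_matrix",
    "gen_group_accuracies",
    "gen_lesion_image",
]


@dataclass
class LesionFixture:
    image: np.ndarray            # H×W×3 in [0, 1]
    mask: np.ndarray             # boolean ground truth
    contrast_gap: float          # requested lightness gap
    measured_gap: float          # achieved mean lightness gap
    nominal_area: float          # requested ellipse area in pixels
    seed: int


@dataclass
class FeatureFixture:
    matrix: FeatureMatrix
    informative_idx: np.ndarray
    redundant_idx: np.ndarray
    noise_idx: np.ndarray
    separation: float
    seed: int


def gen_lesion_image(
    size: int = 128,
    contrast_gap: float = 0.12,
    hair_count: int = 3,
    texture_sd: float = 0.03,
    seed: int = 42,
) -> LesionFixture:
    """Synthetic dermoscopy-like image with a known lesion mask.

    The background lightness sits near 0.65 with Gaussian texture of
    standard deviation ``texture_sd``; the lesion is an ellipse whose radius
    is modulated by a random low-order harmonic series (irregular border)
    and whose interior is darker by ``contrast_gap`` with a softly blurred
    edge.  Hairs are thin dark quadratic curves.  The defaults produce the
    low-contrast regime that motivates contrast stretching.
    """
    if size < 32:
        raise ValueError("size must be at least 32")
    if not 0.0 <= contrast_gap <= 0.8:
        raise ValueError("contrast_gap must lie in [0, 0.8]")
    rng = np.random.default_rng(seed)

    light = 0.65 + rng.normal(0.0, texture_sd, size=(size, size))

    cy, cx = (size / 2 + rng.uniform(-size / 16, size / 16, size=2))
    ry = size * rng.uniform(0.18, 0.26)
    rx = size * rng.uniform(0.18, 0.26)
    amps = rng.uniform(0.0, 0.06, size=4)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)

    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) / rx
    v = (yy - cy) / ry
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    border = 1.0 + sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases))
    )
    mask = rho <= border

    soft = ndimage.gaussian_filter(mask.astype(float), sigma=1.5)
    light -= contrast_gap * soft

    for _ in range(hair_count):
        # quadratic Bezier stroke rendered as a chain of gaussian dabs
        pts = rng.uniform(0, size, size=(3, 2))
        t = np.linspace(0.0, 1.0, 4 * size)[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2])
        stroke = np.zeros((size, size))
        ij = np.round(curve).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
        stroke[ij[keep, 1], ij[keep, 0]] = 1.0
        stroke = ndimage.gaussian_filter(stroke, sigma=0.7)
        if stroke.max() > 0:
            stroke /= stroke.max()
        light -= 0.25 * stroke

    light = np.clip(light, 0.0, 1.0)
    hue = np.full_like(light, 25.0)                 # skin-like hue (degrees)
    sat = np.clip(0.40 + 0.15 * soft, 0.0, 1.0)     # lesion slightly browner
    image = hsl_to_rgb(hue, sat, light)

    measured = float(light[~mask].mean() - light[mask].mean())
    return LesionFixture(
        image=image,
        mask=mask,
        contrast_gap=contrast_gap,
        measured_gap=measured,
        nominal_area=float(np.pi * rx * ry),
        seed=seed,
    )


def gen_feature_matrix(
    n_samples: int = 200,
    n_informative: int = 5,
    n_redundant: int = 5,
    n_noise: int = 40,
    separation: float = 3.0,
    seed: int = 42,
) -> FeatureFixture:
    """Two-class feature matrix with known column roles.

    Informative columns are Gaussians centred at ``±separation/2`` (unit
    noise SD, so the separation is in noise-SD units); redundant columns are
    scaled copies of informative parents plus small noise (|r| > 0.9); noise
    columns are standard Gaussians.  Columns are shuffled and the index sets
    of each role recorded.
    """
    d = n_informative + n_redundant + n_noise
    if d == 0:
        raise ValueError("need at least one feature column")
    if n_redundant > 0 and n_informative == 0:
        raise ValueError("redundant columns need informative parents")
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    rng = np.random.default_rng(seed)

    y = np.zeros(n_samples, dtype=int)
    y[n_samples // 2 :] = 1
    sign = np.where(y == 0, -1.0, 1.0)

    cols = []
    informative = [
        sign * separation / 2.0 + rng.normal(size=n_samples)
        for _ in range(n_informative)
    ]
    cols.extend(informative)
    for j in range(n_redundant):
        parent = informative[j % n_informative]
        scale = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        cols.append(scale * parent + rng.normal(0.0, 0.1, size=n_samples))
    for _ in range(n_noise):
        cols.append(rng.normal(size=n_samples))
    values = np.column_stack(cols)

    perm = rng.permutation(d)
    values = values[:, perm]
    inv = np.argsort(perm)
    informative_idx = np.sort(inv[:n_informative])
    redundant_idx = np.sort(inv[n_informative : n_informative + n_redundant])
    noise_idx = np.sort(inv[n_informative + n_redundant :])

    matrix = FeatureMatrix(values=values, provenance=["SYN"] * d, labels=y)
    return FeatureFixture(
        matrix=matrix,
        informative_idx=informative_idx,
        redundant_idx=redundant_idx,
        noise_idx=noise_idx,
        separation=separation,
        seed=seed,
    )


def gen_group_accuracies(
    means, sd: float = 1.0, n_per_group: int = 5, seed: int = 42
) -> list[np.ndarray]:
    """Gaussian accuracy samples, one array per group mean."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    return [rng.normal(m, sd, size=n_per_group) for m in np.asarray(means, float)]
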