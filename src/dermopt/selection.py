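"""Entropy-controlled whale-optimization wrapper feature selection.

Whale agents hold continuous positions in ``[0, 1]^d``; thresholding a
position at 0.5 yields a candidate feature mask.  Each iteration an agent
either exploits — shrinking encirclement of the best agent when the
coefficient ``|A| ≤ 1``, a logarithmic-spiral move around it otherwise — or
explores toward a randomly chosen agent, the branch taken with probability
``τ = 0.5``.  The coefficient amplitude decays linearly (``α: 2 → 0``), so
exploration dominates early and exploitation late.

The fitness of a candidate mask is built from Shannon entropy.  With labels
present (the default mode) each feature is scored by its information gain
``IG_j = H(y) − H(y | x_j)`` — the reduction in label entropy achieved by
observing the (quantile-binned) feature — and a mask scores the sum of its
normalized gains minus a sparsity penalty ``λ_s·k/d``.  Features whose share
of the total information falls below the per-feature penalty are dropped,
which is what drives the large reduction percentages.  Without labels the
fitness falls back to the normalized entropy of the selected features'
variance distribution, which favours evenly informative subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from dermopt.fusion import FeatureMatrix, reduction_percentage

__all__ = [
    "SelectionResult",
    "WhaleConfig",
    "coefficients",
    "explore",
    "select_features",
    "selection_fitness",
    "shannon_entropy",
    "shrinking_encircle",
    "spiral_update",
]


@dataclass(frozen=True)
class WhaleConfig:
    agents: int = 30
    max_iter: int = 100
    spiral_b: float = 1.0         # geometry of the logarithmic spiral
    tau: float = 0.5              # exploitation-branch probability
    threshold: float = 0.5        # position > threshold selects the feature
    sparsity_weight: float = 0.5  # λ_s; total penalty at full selection
    fitness_mode: str = "info_gain"   # or "variance_entropy"
    n_bins: int = 8               # quantile bins for information gain
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.fitness_mode not in ("info_gain", "variance_entropy"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")


@dataclass
class SelectionResult:
    mask: np.ndarray
    selected: FeatureMatrix
    reduction_pct: int
    fitness: float
    best_position: np.ndarray
    trace: list[float] = field(default_factory=list)


def coefficients(t: int, max_iter: int, rho_r):
    """Iteration-``t`` coefficients: ``α = 2 − 2t/Itermax``, ``A = 2αρ − α``,
    ``C = 2ρ`` for a uniform draw ``ρ ∈ [0, 1]`` (scalar or elementwise)."""
    alpha = 2.0 - 2.0 * t / max_iter
    rho_r = np.asarray(rho_r, dtype=float)
    a_vec = 2.0 * alpha * rho_r - alpha
    c_vec = 2.0 * rho_r
    if a_vec.ndim == 0:
        return alpha, float(a_vec), float(c_vec)
    return alpha, a_vec, c_vec


def _clip01(x):
    return np.clip(x, 0.0, 1.0)


def shrinking_encircle(pos, best, a_coef, c_coef):
    """``O' = clip(Obest − A·|C·Obest − O|)``."""
    return _clip01(best - a_coef * np.abs(c_coef * best - pos))


def spiral_update(pos, best, b: float, ell: float):
    """``O' = clip(|Obest − O|·e^{b·l}·cos(2πl) + Obest)`` for ``l ∈ [−1, 1]``."""
    dist = np.abs(best - pos)
    return _clip01(dist * np.exp(b * ell) * np.cos(2.0 * np.pi * ell) + best)


def explore(pos, rand_pos, a_coef, c_coef):
    """``O' = clip(Orand − A·|C·Orand − O|)`` toward a random agent."""
    return _clip01(rand_pos - a_coef * np.abs(c_coef * rand_pos - pos))


def shannon_entropy(probs) -> float:
    """Shannon entropy in bits, with ``0·log 0 = 0``.

    Input should be a probability vector; anything positive that does not
    sum to one (within 1e-9) is renormalized with a warning.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        warnings.warn("probabilities renormalized to sum to 1", stacklevel=2)
        if total <= 0:
            raise ValueError("cannot normalize an all-zero vector")
        p = p / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _label_entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    return shannon_entropy(counts / counts.sum())


def information_gain_weights(features: FeatureMatrix, n_bins: int = 8) -> np.ndarray:
    """Normalized per-feature information gain about the labels.

    Each column is quantile-binned and scored by ``H(y) − H(y | bin)``; the
    gains are normalized to sum to one across all columns, so a weight is a
    feature's share of the total label information carried individually.
    """
    if features.labels is None:
        raise ValueError("information gain requires labels")
    x = features.values
    y = np.asarray(features.labels)
    h_y = _label_entropy(y)
    n, d = x.shape
    gains = np.zeros(d)
    classes = np.unique(y)
    y_idx = np.searchsorted(classes, y)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(d):
        edges = np.unique(np.quantile(x[:, j], qs))
        bins = np.searchsorted(edges, x[:, j], side="right")
        cond = 0.0
        for b in np.unique(bins):
            sel = bins == b
            w = sel.mean()
            counts = np.bincount(y_idx[sel], minlength=classes.size)
            cond += w * shannon_entropy(counts / counts.sum())
        gains[j] = max(h_y - cond, 0.0)
    total = gains.sum()
    if total <= 0:
        return np.full(d, 1.0 / d)
    return gains / total


def _variance_entropy_fitness(
    mask: np.ndarray, values: np.ndarray, sparsity_weight: float
) -> float:
    k = int(mask.sum())
    d = mask.size
    if k < 2:
        return -np.inf
    variances = values[:, mask].var(axis=0)
    total = variances.sum()
    if total <= 0:
        return -np.inf
    eta = variances / total
    return shannon_entropy(eta) / np.log2(k) - sparsity_weight * k / d


def _info_gain_fitness(
    mask: np.ndarray, weights: np.ndarray, sparsity_weight: float
) -> float:
    k = int(mask.sum())
    if k < 2:
        return -np.inf
    return float(weights[mask].sum()) - sparsity_weight * k / mask.size


def selection_fitness(
    position: np.ndarray, features: FeatureMatrix, cfg: WhaleConfig
) -> float:
    """Fitness of the mask obtained by thresholding ``position``.

    Returns ``−inf`` for degenerate masks (fewer than two features, or only
    zero-variance features in the variance mode).
    """
    mask = np.asarray(position) > cfg.threshold
    if cfg.fitness_mode == "info_gain" and features.labels is not None:
        weights = information_gain_weights(features, cfg.n_bins)
        return _info_gain_fitness(mask, weights, cfg.sparsity_weight)
    return _variance_entropy_fitness(mask, features.values, cfg.sparsity_weight)


def select_features(
    features: FeatureMatrix, cfg: WhaleConfig | None = None
) -> SelectionResult:
    """Run the whale search and return the selected sub-matrix.

    The best agent's thresholded position is the final mask; if it is empty
    the top ``⌈d/4⌉`` coordinates of the best position are taken instead
    (with a warning).
    """
    cfg = cfg or WhaleConfig()
    d = features.n_features
    if d < 2 or features.n_samples < 2:
        raise ValueError("need at least 2 features and 2 samples")
    use_ig = cfg.fitness_mode == "info_gain" and features.labels is not None
    if use_ig:
        weights = information_gain_weights(features, cfg.n_bins)

        def fitness_of(pos: np.ndarray) -> float:
            return _info_gain_fitness(pos > cfg.threshold, weights,
                                      cfg.sparsity_weight)
    else:

        def fitness_of(pos: np.ndarray) -> float:
            return _variance_entropy_fitness(pos > cfg.threshold,
                                             features.values,
                                             cfg.sparsity_weight)

    rng = np.random.default_rng(cfg.seed)
    pos = rng.uniform(size=(cfg.agents, d))
    fits = np.array([fitness_of(p) for p in pos])
    best_idx = int(np.argmax(fits))
    best = pos[best_idx].copy()
    best_fit = float(fits[best_idx])
    trace = [best_fit]

    for t in range(1, cfg.max_iter + 1):
        for j in range(cfg.agents):
            rho_r = rng.uniform()
            _, a_coef, c_coef = coefficients(t, cfg.max_iter, rho_r)
            rho = rng.uniform()
            ell = rng.uniform(-1.0, 1.0)
            if rho < cfg.tau:
                if abs(a_coef) <= 1.0:
                    pos[j] = shrinking_encircle(pos[j], best, a_coef, c_coef)
                else:
                    pos[j] = spiral_update(pos[j], best, cfg.spiral_b, ell)
            else:
                rand_pos = pos[int(rng.integers(cfg.agents))]
                pos[j] = explore(pos[j], rand_pos, a_coef, c_coef)
        fits = np.array([fitness_of(p) for p in pos])
        t_best = int(np.argmax(fits))
        if fits[t_best] > best_fit:
            best_fit = float(fits[t_best])
            best = pos[t_best].copy()
        trace.append(best_fit)

    mask = best > cfg.threshold
    if not mask.any():
        warnings.warn(
            "whale search selected no features; keeping top quarter by "
            "position magnitude",
            stacklevel=2,
        )
        keep = int(np.ceil(d / 4))
        mask = np.zeros(d, dtype=bool)
        mask[np.argsort(best)[::-1][:keep]] = True
    selected = FeatureMatrix(
        values=features.values[:, mask],
        provenance=[tag for tag, m in zip(features.provenance, mask) if m],
        labels=features.labels,
    )
    return SelectionResult(
        mask=mask,
        selected=selected,
        reduction_pct=reduction_percentage(d, int(mask.sum())),
        fitness=best_fit,
        best_position=best,
        trace=trace,
    )
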