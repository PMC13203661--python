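"""Artificial-bee-colony refinement with an entropy-augmented fitness.

Food sources (candidate parameter vectors) are improved through employed,
onlooker and scout phases with greedy replacement.  The fitness that drives
roulette selection is the canonical ABC mapping of a minimized cost ``C``
(``1 + |C|`` when negative, ``1/(1 + C)`` otherwise) minus an entropy term
``α_e·H`` where ``H`` is the Shannon entropy (bits) of the source's
bounds-normalized coordinates.  The entropy term nudges selection pressure
by the disorder of the parameter vector itself; ``α_e = 0`` recovers the
canonical algorithm exactly.  The caller's objective is *maximized*: the
quality value ``q`` is fed to the fitness map as ``C = −q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeeConfig",
    "BeeResult",
    "entropy_of_source",
    "fitness_map",
    "neighbor",
    "onlooker_probs",
    "run_abc",
]

_FITNESS_FLOOR = 1e-12


@dataclass(frozen=True)
class BeeConfig:
    max_iter: int = 50
    limit: int = 20          # failed trials before a scout abandons a source
    entropy_weight: float = 0.1   # α_e; 0 disables (canonical ABC); may be <0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.limit < 1:
            raise ValueError("limit must be >= 1")


@dataclass
class BeeResult:
    best_position: np.ndarray
    best_cost: float
    population: np.ndarray
    costs: np.ndarray
    trace: list[float] = field(default_factory=list)


def entropy_of_source(source, lower, upper) -> float:
    """Shannon entropy (bits) of the bounds-normalized coordinate weights.

    Coordinates are mapped to [0, 1] by their bounds and renormalized to sum
    to one (uniform if all zero); the entropy of that weight vector measures
    how evenly the source spreads across its box.
    """
    source = np.asarray(source, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    z = (source - lower) / (upper - lower)
    total = z.sum()
    if total <= 0.0:
        w = np.full(z.size, 1.0 / z.size)
    else:
        w = z / total
    w = w[w > 0]
    return float(-(w * np.log2(w)).sum())


def fitness_map(quality: float, entropy: float, entropy_weight: float) -> float:
    """Map a maximized quality value to an ABC selection fitness.

    The minimized surrogate is ``C = −quality``; the canonical base fitness
    is ``1 + |C|`` for ``C < 0`` and ``1/(1 + C)`` otherwise, from which
    ``α_e·H`` is subtracted.  The result is floored at a tiny positive value
    so roulette probabilities stay well defined.
    """
    c = -quality
    base = 1.0 + abs(c) if c < 0 else 1.0 / (1.0 + c)
    return max(base - entropy_weight * entropy, _FITNESS_FLOOR)


def neighbor(source, partner, phi: float, coord: int, lower, upper):
    """Candidate differing from ``source`` in one coordinate:
    ``x_j + φ·(x_j − partner_j)``, clipped to bounds."""
    cand = np.asarray(source, dtype=float).copy()
    cand[coord] += phi * (cand[coord] - np.asarray(partner)[coord])
    return np.clip(cand, lower, upper)


def onlooker_probs(fitness: np.ndarray) -> np.ndarray:
    """Roulette probabilities ``p_i = fit_i / Σ fit`` (uniform if all zero)."""
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness < 0):
        raise ValueError("fitness values must be non-negative")
    total = fitness.sum()
    if total <= 0:
        return np.full(fitness.size, 1.0 / fitness.size)
    return fitness / total


def run_abc(
    objective_fn,
    init_population: np.ndarray,
    lower,
    upper,
    cfg: BeeConfig,
    rng: np.random.Generator | None = None,
) -> BeeResult:
    """Refine ``init_population`` by maximizing ``objective_fn`` on the box.

    One iteration = employed phase (one neighbour per source, greedy
    replacement), onlooker phase (fitness-proportional source choice, same
    move), scout phase (re-randomize any source whose trial counter exceeds
    ``cfg.limit``).  ``cfg.max_iter == 0`` returns the population unchanged.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = np.clip(np.asarray(init_population, dtype=float), lower, upper).copy()
    n, dim = pop.shape
    costs = np.array([objective_fn(pop[i]) for i in range(n)])
    trials = np.zeros(n, dtype=int)

    best_idx = int(np.argmax(costs))
    best = pop[best_idx].copy()
    best_cost = float(costs[best_idx])
    trace = [best_cost]

    def _fitness(i: int) -> float:
        h = entropy_of_source(pop[i], lower, upper)
        return fitness_map(costs[i], h, cfg.entropy_weight)

    def _try_move(i: int) -> None:
        nonlocal best, best_cost
        partner = int(rng.integers(n - 1))
        if partner >= i:
            partner += 1
        coord = int(rng.integers(dim))
        phi = rng.uniform(-1.0, 1.0)
        cand = neighbor(pop[i], pop[partner], phi, coord, lower, upper)
        cand_cost = objective_fn(cand)
        if cand_cost > costs[i]:
            pop[i] = cand
            costs[i] = cand_cost
            trials[i] = 0
            if cand_cost > best_cost:
                best_cost = float(cand_cost)
                best = cand.copy()
        else:
            trials[i] += 1

    for _ in range(cfg.max_iter):
        for i in range(n):          # employed bees
            _try_move(i)
        fits = np.array([_fitness(i) for i in range(n)])
        probs = onlooker_probs(fits)
        for _ in range(n):          # onlooker bees
            i = int(rng.choice(n, p=probs))
            _try_move(i)
        for i in range(n):          # scouts
            if trials[i] > cfg.limit:
                pop[i] = rng.uniform(lower, upper, size=dim)
                costs[i] = objective_fn(pop[i])
                trials[i] = 0
                if costs[i] > best_cost:
                    best_cost = float(costs[i])
                    best = pop[i].copy()
        trace.append(best_cost)

    return BeeResult(
        best_position=best,
        best_cost=best_cost,
        population=pop,
        costs=costs,
        trace=trace,
    )
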