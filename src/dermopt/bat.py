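"""Modified bat-algorithm search over a bounded box.

Bats carry a position (a candidate parameter vector), a velocity, a loudness
``λ`` and a pulse rate ``P``.  Each iteration a bat draws a frequency
``ω = ωmin + (ωmax − ωmin)·β``, updates its velocity with an extra centred
random term ``α·(u − ν_thresh)`` that injects diversity, and moves.  With
probability ``1 − P`` it instead takes a local random walk around the global
best scaled by the mean loudness.  A candidate is accepted when it improves
the bat's own objective value *and* a uniform draw falls below the bat's
loudness; acceptance decays the loudness geometrically and raises the pulse
rate toward its asymptote, shifting the search from exploration to
exploitation.  The objective is maximized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BatConfig",
    "BatResult",
    "frequency",
    "local_walk",
    "run_bat",
    "update_loudness_pulse",
    "update_position",
    "update_velocity",
]


@dataclass(frozen=True)
class BatConfig:
    pop_size: int = 50
    max_iter: int = 50
    omega_min: float = 0.0
    omega_max: float = 2.0
    alpha_rand: float = 0.5       # weight of the random velocity term
    nu_thresh: float = 0.5        # break parameter, in [0.45, 0.55]
    loudness_decay: float = 0.9   # ϑ, geometric loudness decay per acceptance
    pulse_growth: float = 0.9     # ϱ, pulse-rate rise rate
    loudness_init: float = 1.0
    pulse_max: float = 0.9        # asymptotic pulse rate P0
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.omega_min < self.omega_max:
            raise ValueError("omega_min must be < omega_max")
        if not 0.45 <= self.nu_thresh <= 0.55:
            raise ValueError("nu_thresh must lie in [0.45, 0.55]")
        if not 0.0 < self.loudness_decay < 1.0:
            raise ValueError("loudness_decay must lie in (0, 1)")
        if self.pulse_growth <= 0.0:
            raise ValueError("pulse_growth must be positive")


@dataclass
class BatResult:
    best_position: np.ndarray
    best_cost: float
    population: np.ndarray
    costs: np.ndarray
    trace: list[float] = field(default_factory=list)


def frequency(cfg: BatConfig, beta: float) -> float:
    """Frequency ``ω = ωmin + (ωmax − ωmin)·β`` for a draw ``β ∈ [0, 1]``."""
    return cfg.omega_min + (cfg.omega_max - cfg.omega_min) * beta


def update_velocity(v_prev, d_i, d_best, omega, alpha_rand, nu_thresh, u):
    """``ν' = ω·(d − d*) + ν + α·(u − ν_thresh)`` elementwise."""
    return omega * (np.asarray(d_i) - np.asarray(d_best)) + np.asarray(v_prev) + (
        alpha_rand * (np.asarray(u) - nu_thresh)
    )


def update_position(d_i, v_new, d_best, beta, alpha_rand, u, lower, upper):
    """``d' = clip(d + ν' + β·(d − d*)·α·u)`` elementwise."""
    d_i = np.asarray(d_i)
    cand = d_i + np.asarray(v_new) + beta * (d_i - np.asarray(d_best)) * (
        alpha_rand * np.asarray(u)
    )
    return np.clip(cand, lower, upper)


def local_walk(d_old, mean_loudness, pi, lower, upper):
    """Random walk ``d' = clip(d + π·λ̄)`` with per-coordinate ``π ∈ [−1, 1]``."""
    return np.clip(np.asarray(d_old) + np.asarray(pi) * mean_loudness, lower, upper)


def update_loudness_pulse(
    loudness: float, t: int, cfg: BatConfig
) -> tuple[float, float]:
    """Post-acceptance schedules ``λ' = ϑ·λ`` and ``P' = P0·(1 − e^{−ϱ·t})``."""
    return (
        cfg.loudness_decay * loudness,
        cfg.pulse_max * (1.0 - math.exp(-cfg.pulse_growth * t)),
    )


def run_bat(
    objective_fn,
    lower,
    upper,
    cfg: BatConfig,
    init_population: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> BatResult:
    """Maximize ``objective_fn`` over the box ``[lower, upper]``.

    ``init_population`` lets a caller seed the swarm (e.g. to chain
    optimizers); otherwise positions are drawn uniformly in the box.  Returns
    the final population so a downstream stage can take over.  With
    ``cfg.max_iter == 0`` the initialized population is scored and returned
    unchanged.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    dim = lower.size
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if init_population is None:
        pop = rng.uniform(lower, upper, size=(cfg.pop_size, dim))
    else:
        pop = np.clip(np.asarray(init_population, dtype=float), lower, upper).copy()
    n = pop.shape[0]
    costs = np.array([objective_fn(pop[i]) for i in range(n)])
    vel = np.zeros_like(pop)
    loudness = np.full(n, cfg.loudness_init)
    pulse = np.zeros(n)

    best_idx = int(np.argmax(costs))
    best = pop[best_idx].copy()
    best_cost = float(costs[best_idx])
    trace = [best_cost]

    for t in range(1, cfg.max_iter + 1):
        for i in range(n):
            beta = rng.uniform()
            omega = frequency(cfg, beta)
            vel[i] = update_velocity(
                vel[i], pop[i], best, omega, cfg.alpha_rand, cfg.nu_thresh,
                rng.uniform(size=dim),
            )
            cand = update_position(
                pop[i], vel[i], best, beta, cfg.alpha_rand,
                rng.uniform(size=dim), lower, upper,
            )
            if rng.uniform() > pulse[i]:
                cand = local_walk(
                    best, float(loudness.mean()),
                    rng.uniform(-1.0, 1.0, size=dim), lower, upper,
                )
            cand_cost = objective_fn(cand)
            if cand_cost > costs[i] and rng.uniform() < loudness[i]:
                pop[i] = cand
                costs[i] = cand_cost
                loudness[i], pulse[i] = update_loudness_pulse(loudness[i], t, cfg)
            if costs[i] > best_cost:
                best_cost = float(costs[i])
                best = pop[i].copy()
        trace.append(best_cost)

    return BatResult(
        best_position=best,
        best_cost=best_cost,
        population=pop,
        costs=costs,
        trace=trace,
    )
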