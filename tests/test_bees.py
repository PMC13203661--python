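"""Artificial-bee-colony refinement and its entropy-augmented fitness."""

import numpy as np
import pytest

from dermopt.bees import (
    BeeConfig,
    entropy_of_source,
    fitness_map,
    neighbor,
    onlooker_probs,
    run_abc,
)


def test_entropy_of_source_known_values():
    lower, upper = np.zeros(4), np.ones(4)
    assert entropy_of_source(np.full(4, 0.3), lower, upper) == pytest.approx(2.0)
    assert entropy_of_source([0.7, 0, 0, 0], lower, upper) == 0.0
    # weights (0.5, 0.25, 0.25, 0) -> 1.5 bits
    assert entropy_of_source([0.4, 0.2, 0.2, 0.0], lower, upper) == (
        pytest.approx(1.5)
    )
    # all-zero source falls back to uniform weights
    assert entropy_of_source(np.zeros(4), lower, upper) == pytest.approx(2.0)


def test_fitness_map_values():
    # quality 0 -> minimized C = 0 -> 1/(1+0)
    assert fitness_map(0.0, 0.0, 0.0) == 1.0
    # quality -1 -> C = 1 -> 1/2
    assert fitness_map(-1.0, 0.0, 0.0) == 0.5
    # quality 0.5 -> C = -0.5 -> 1 + |C| = 1.5, minus 0.1 * 2
    assert fitness_map(0.5, 2.0, 0.1) == pytest.approx(1.3)
    # floored at a tiny positive value
    assert fitness_map(-100.0, 10.0, 1.0) > 0.0


def test_neighbor_moves_one_coordinate():
    lower, upper = np.zeros(3), np.ones(3)
    src = np.array([0.4, 0.4, 0.4])
    partner = np.array([0.2, 0.2, 0.2])
    cand = neighbor(src, partner, 1.0, 0, lower, upper)
    np.testing.assert_allclose(cand, [0.6, 0.4, 0.4])
    np.testing.assert_array_equal(neighbor(src, partner, 0.0, 1, lower, upper), src)
    cand = neighbor(np.array([0.9, 0, 0]), np.array([0.1, 0, 0]), 1.0, 0,
                    lower, upper)
    assert cand[0] == 1.0  # clipped


def test_onlooker_probs():
    np.testing.assert_allclose(onlooker_probs([1.0, 1.0]), [0.5, 0.5])
    np.testing.assert_allclose(onlooker_probs([3.0, 1.0]), [0.75, 0.25])
    np.testing.assert_allclose(onlooker_probs([2.0]), [1.0])
    np.testing.assert_allclose(onlooker_probs([0.0, 0.0]), [0.5, 0.5])
    with pytest.raises(ValueError):
        onlooker_probs([-1.0, 2.0])


def test_finds_1d_surrogate_optimum():
    rng = np.random.default_rng(42)
    init = rng.uniform(size=(50, 1))
    res = run_abc(lambda x: -((x[0] - 0.7) ** 2), init, [0.0], [1.0],
                  BeeConfig(max_iter=50, seed=42))
    assert abs(res.best_position[0] - 0.7) < 0.02


@pytest.mark.parametrize("seed", range(5))
def test_trace_monotone_and_greedy_never_degrades(seed):
    rng = np.random.default_rng(seed)
    init = rng.uniform(size=(8, 3))
    f = lambda x: -np.sum((x - 0.4) ** 2)  # noqa: E731
    init_costs = np.array([f(p) for p in init])
    res = run_abc(f, init, np.zeros(3), np.ones(3),
                  BeeConfig(max_iter=15, seed=seed))
    assert np.all(np.diff(res.trace) >= 0)
    assert np.all(res.population >= 0) and np.all(res.population <= 1)
    # greedy replacement: a surviving (non-scouted) source never got worse;
    # with a generous limit no scout fires, so this holds for every source
    assert np.all(res.costs >= init_costs - 1e-12)


def test_zero_budget_is_identity():
    init = np.random.default_rng(1).uniform(size=(5, 2))
    res = run_abc(lambda x: float(x.sum()), init, np.zeros(2), np.ones(2),
                  BeeConfig(max_iter=0, seed=1))
    np.testing.assert_array_equal(res.population, init)


def _canonical_abc_oracle(f, init, lower, upper, max_iter, limit, seed):
    """Independent canonical ABC (no entropy term) mirroring the documented
    draw protocol: employed sweep, fitness-proportional onlookers, scouts."""
    rng = np.random.default_rng(seed)
    pop = init.copy()
    n, dim = pop.shape
    costs = np.array([f(p) for p in pop])
    trials = np.zeros(n, dtype=int)
    best = pop[np.argmax(costs)].copy()
    best_cost = costs.max()
    trace = [best_cost]

    def move(i):
        nonlocal best, best_cost
        partner = int(rng.integers(n - 1))
        if partner >= i:
            partner += 1
        coord = int(rng.integers(dim))
        phi = rng.uniform(-1.0, 1.0)
        cand = pop[i].copy()
        cand[coord] += phi * (cand[coord] - pop[partner][coord])
        cand = np.clip(cand, lower, upper)
        c = f(cand)
        if c > costs[i]:
            pop[i], costs[i], trials[i] = cand, c, 0
            if c > best_cost:
                best_cost, best = c, cand.copy()
        else:
            trials[i] += 1

    for _ in range(max_iter):
        for i in range(n):
            move(i)
        minimized = -costs
        fit = np.where(minimized < 0, 1 + np.abs(minimized), 1 / (1 + minimized))
        probs = fit / fit.sum()
        for _ in range(n):
            move(int(rng.choice(n, p=probs)))
        for i in range(n):
            if trials[i] > limit:
                pop[i] = rng.uniform(lower, upper, size=dim)
                costs[i] = f(pop[i])
                trials[i] = 0
                if costs[i] > best_cost:
                    best_cost, best = costs[i], pop[i].copy()
        trace.append(best_cost)
    return pop, trace


def test_zero_entropy_weight_matches_canonical_oracle():
    rng = np.random.default_rng(9)
    init = rng.uniform(size=(6, 2))
    f = lambda x: -np.sum((x - 0.25) ** 2)  # noqa: E731
    res = run_abc(f, init, np.zeros(2), np.ones(2),
                  BeeConfig(max_iter=12, limit=5, entropy_weight=0.0, seed=99))
    pop, trace = _canonical_abc_oracle(f, init, np.zeros(2), np.ones(2),
                                       max_iter=12, limit=5, seed=99)
    np.testing.assert_array_equal(res.population, pop)
    np.testing.assert_allclose(res.trace, trace)


def test_scout_triggers_after_limit():
    # an objective where no neighbour move can ever improve: f constant, so
    # every trial fails and scouts must fire once trials exceed the limit
    init = np.full((3, 2), 0.5)
    res = run_abc(lambda x: 0.0, init, np.zeros(2), np.ones(2),
                  BeeConfig(max_iter=4, limit=2, seed=0))
    # after 4 iterations (8 failed moves minimum) each source was re-seeded
    assert not np.allclose(res.population, init)


def test_config_validation():
    with pytest.raises(ValueError):
        BeeConfig(limit=0)
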