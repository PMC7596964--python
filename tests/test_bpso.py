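"""Binary swarm optimizer: update rule mechanics, elitism, oracle checks."""

import numpy as np
import pytest

from dcfs.bpso import (
    BPSOParams,
    Swarm,
    bpso_optimize,
    bpso_step,
    cv_f1_fitness,
    exhaustive_search,
    init_swarm,
    merit_fitness,
    sigmoid,
)
from dcfs.simulate import SimSpec, generate


def popcount_fitness(mask):
    return float(mask.sum())


def test_velocity_clamped_and_positions_binary(rng):
    params = BPSOParams(n_particles=20, n_iterations=1, v_min=-6, v_max=6)
    swarm = init_swarm(popcount_fitness, 12, params, rng)
    swarm.v[:] = 50.0  # force an out-of-range pre-update velocity
    for _ in range(5):
        bpso_step(swarm, popcount_fitness, params, rng)
        assert swarm.v.min() >= params.v_min and swarm.v.max() <= params.v_max
        assert set(np.unique(swarm.x)).issubset({0, 1})


def test_stationary_particle_velocity_fixed_point(rng):
    """pb = gb = x and v = 0 leaves v at 0; the bit then resamples at
    probability sigmoid(0) = 1/2."""
    params = BPSOParams(n_particles=1, n_iterations=1)
    x = np.ones((1, 4), dtype=np.int8)
    swarm = Swarm(x=x.copy(), v=np.zeros((1, 4)), pb=x.copy(),
                  pb_fitness=np.array([4.0]), gb=x[0].copy(), gb_fitness=4.0)
    draws = []
    for seed in range(40):
        s = Swarm(x=x.copy(), v=np.zeros((1, 4)), pb=x.copy(),
                  pb_fitness=np.array([4.0]), gb=x[0].copy(), gb_fitness=4.0)
        bpso_step(s, popcount_fitness, params, np.random.default_rng(seed))
        assert np.all(s.v == 0.0)
        draws.append(s.x.mean())
    assert 0.3 < np.mean(draws) < 0.7  # ~Bernoulli(1/2) bits
    assert sigmoid(0.0) == 0.5


def test_personal_best_keeps_incumbent_on_ties(rng):
    params = BPSOParams(n_particles=5, n_iterations=1)
    const = lambda mask: 1.0
    swarm = init_swarm(const, 6, params, rng)
    pb_before = swarm.pb.copy()
    bpso_step(swarm, const, params, rng)
    np.testing.assert_array_equal(swarm.pb, pb_before)
    assert swarm.gb_fitness == 1.0


def test_global_best_fitness_nondecreasing(rng):
    params = BPSOParams(n_particles=10, n_iterations=1)
    fitness = lambda mask: float(np.sin(mask.sum()) + mask[0])
    swarm = init_swarm(fitness, 9, params, rng)
    trace = [swarm.gb_fitness]
    for _ in range(30):
        bpso_step(swarm, fitness, params, rng)
        trace.append(swarm.gb_fitness)
    assert np.all(np.diff(trace) >= 0)


def test_same_seed_identical_result():
    res1 = bpso_optimize(popcount_fitness, 10, BPSOParams(n_particles=15, n_iterations=20), seed=5)
    res2 = bpso_optimize(popcount_fitness, 10, BPSOParams(n_particles=15, n_iterations=20), seed=5)
    np.testing.assert_array_equal(res1.mask, res2.mask)
    assert res1.fitness == res2.fitness


def test_constant_fitness_returns_valid_mask():
    res = bpso_optimize(lambda m: 0.25, 7, BPSOParams(n_particles=8, n_iterations=5), seed=0)
    assert res.mask.shape == (7,)
    assert res.fitness == 0.25
    assert res.n_selected == int(res.mask.sum())


def test_finds_known_optimum_popcount():
    res = bpso_optimize(popcount_fitness, 8, BPSOParams(n_particles=30, n_iterations=40), seed=1)
    assert res.fitness == 8.0


def test_exhaustive_search_is_a_true_maximum():
    weights = np.array([3.0, -1.0, 2.0, -4.0, 0.5])
    fitness = lambda m: float(weights[m].sum())
    mask, val = exhaustive_search(fitness, 5)
    assert mask.tolist() == [True, False, True, False, True]
    assert val == 5.5


def test_swarm_matches_exhaustive_on_planted_merit():
    """On a 10-feature planted instance the swarm optimum equals the
    brute-force merit optimum over all 1023 subsets."""
    spec = SimSpec(n_samples=150, n_features=10, n_pos_assoc=1, n_neg_assoc=1,
                   effect=0.6, background_rate=0.1, seed=4)
    fm, _ = generate(spec)
    fitness = merit_fitness(fm.X, fm.c_pos)
    oracle_mask, oracle_val = exhaustive_search(fitness, 10)
    hits = 0
    for seed in range(5):
        res = bpso_optimize(fitness, 10, seed=seed)
        if res.fitness == pytest.approx(oracle_val, abs=1e-12):
            hits += 1
    assert hits >= 4


def test_cv_f1_fitness_contract(planted_cohort):
    fm, truth = planted_cohort
    fitness = cv_f1_fitness(fm.X, fm.c_pos, k=5, seed=0)
    empty = np.zeros(fm.n_features, dtype=bool)
    assert fitness(empty) == 0.0
    label_like = np.zeros(fm.n_features, dtype=bool)
    # a feature identical to the labels is perfectly separable
    X = fm.X.copy()
    X[:, 0] = fm.c_pos
    fitness = cv_f1_fitness(X, fm.c_pos, k=5, seed=0)
    label_like[0] = True
    assert fitness(label_like) == pytest.approx(1.0)


def test_all_noise_features_score_near_chance(rng):
    """Permutation-null: noise-only features under a linear classifier
    give CV F1 near the chance level."""
    X = (rng.random((200, 5)) < 0.3).astype(float)
    y = np.repeat([1, 0], 100)
    fitness = cv_f1_fitness(X, y, k=10, seed=0)
    f1 = fitness(np.ones(5, dtype=bool))
    assert 0.3 < f1 < 0.7


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        BPSOParams(v_min=6, v_max=-6)
    with pytest.raises(ValueError):
        BPSOParams(n_particles=0)
    with pytest.raises(ValueError):
        bpso_optimize(popcount_fitness, 0)
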