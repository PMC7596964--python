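"""CFS/dual merit: worked values, scalarization algebra, invariances."""

import numpy as np
import pytest

from dcfs.merit import (
    MeritEngine,
    MeritParams,
    cfs_merit,
    dcfs_merit,
    mean_feature_class_corr,
    mean_feature_feature_corr,
    merit_from_means,
)


@pytest.fixture
def c4():
    return np.array([1, 1, 0, 0])


def test_mean_feature_feature_identical_and_anticorrelated(c4):
    X = np.stack([c4, c4, 1 - c4], axis=1).astype(float)
    # identical pair
    assert mean_feature_feature_corr(X, [1, 1, 0]) == pytest.approx(1.0)
    # perfectly anticorrelated pair enters absolutely
    assert mean_feature_feature_corr(X, [1, 0, 1]) == pytest.approx(1.0)


def test_mean_feature_feature_three_columns(rng):
    """Pairwise |rho| = (1, 0, 0) over the three unordered pairs -> 1/3."""
    a = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    b = a.copy()                     # |rho(a,b)| = 1
    c = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])  # orthogonal to the trend
    c = c - np.polyval(np.polyfit(a, c, 1), a)    # force rho(a,c)=0 exactly
    X = np.stack([a, b, c], axis=1)
    got = mean_feature_feature_corr(X, [1, 1, 1])
    assert got == pytest.approx(1 / 3, abs=1e-10)


def test_mean_feature_class_corr_policies(c4):
    X = np.stack([c4, 1 - c4], axis=1).astype(float)
    clip = MeritParams()
    assert mean_feature_class_corr(X, [1, 0], c4, clip) == pytest.approx(1.0)
    assert mean_feature_class_corr(X, [0, 1], c4, clip) == 0.0
    assert mean_feature_class_corr(X, [1, 1], c4, clip) == pytest.approx(0.5)
    assert mean_feature_class_corr(
        X, [0, 1], c4, MeritParams(negative_correlation_policy="absolute")
    ) == pytest.approx(1.0)
    assert mean_feature_class_corr(
        X, [0, 1], c4, MeritParams(negative_correlation_policy="signed")
    ) == pytest.approx(-1.0)


def test_merit_from_means_algebra():
    assert merit_from_means(1, 0.8, 0.0) == pytest.approx(0.8)
    assert merit_from_means(2, 0.5, 0.0) == pytest.approx(2 * 0.5 / np.sqrt(2))
    assert merit_from_means(0, 0.9, 0.5) == 0.0
    assert merit_from_means(3, 0.0, 0.2) == 0.0


def test_cfs_merit_degenerate_masks(c4):
    X = np.stack([c4, 1 - c4], axis=1).astype(float)
    assert cfs_merit(X, [0, 0], c4) == 0.0
    # singleton reduces to its (clipped) class correlation
    assert cfs_merit(X, [1, 0], c4) == pytest.approx(1.0)
    assert cfs_merit(X, [0, 1], c4) == 0.0


def test_dual_merit_worked_example(c4):
    """One feature per class, mutually anticorrelated, alpha=0.5 -> 0.5."""
    X = np.stack([c4, 1 - c4], axis=1).astype(float)
    assert dcfs_merit(X, [1, 1], c4, MeritParams(alpha=0.5)) == pytest.approx(0.5)


@pytest.mark.parametrize("alpha", [0.0, 1.0])
def test_scalarization_endpoints(rng, alpha):
    X = rng.random((40, 8))
    c = (rng.random(40) < 0.5).astype(float)
    mask = rng.random(8) < 0.5
    dual = dcfs_merit(X, mask, c, MeritParams(alpha=alpha))
    single = cfs_merit(X, mask, c if alpha == 1.0 else 1 - c)
    assert dual == single  # exact floating-point agreement


def test_linearity_in_alpha(rng):
    X = rng.random((30, 6))
    c = (rng.random(30) < 0.5).astype(float)
    mask = np.array([1, 0, 1, 1, 0, 1])
    vals = {a: dcfs_merit(X, mask, c, MeritParams(alpha=a)) for a in (0.0, 0.5, 1.0)}
    assert vals[0.5] == pytest.approx((vals[0.0] + vals[1.0]) / 2, abs=1e-12)


def test_permutation_invariance(rng):
    X = rng.random((25, 7))
    c = (rng.random(25) < 0.4).astype(float)
    mask = np.array([1, 1, 0, 1, 0, 0, 1])
    base = dcfs_merit(X, mask, c)
    fperm = rng.permutation(7)
    assert dcfs_merit(X[:, fperm], mask[fperm], c) == pytest.approx(base, abs=1e-12)
    sperm = rng.permutation(25)
    assert dcfs_merit(X[sperm], mask, c[sperm]) == pytest.approx(base, abs=1e-12)


def test_duplicate_feature_does_not_increase_merit(c4):
    """Adding an exact copy of a selected feature whose class correlation
    does not exceed the current mean cannot raise the merit (the
    denominator's redundancy penalty dominates)."""
    c8 = np.repeat(c4, 2)
    noise = np.array([1, 0, 0, 1, 1, 0, 1, 0], dtype=float)
    X = np.stack([c8, noise, noise], axis=1)
    before = cfs_merit(X, [1, 1, 0], c8)
    with_dup = cfs_merit(X, [1, 1, 1], c8)
    assert with_dup <= before + 1e-12


def test_engine_precompute_paths_agree(rng):
    X = (rng.random((50, 12)) < 0.3).astype(float)
    c = (rng.random(50) < 0.5).astype(float)
    for method in ("pearson", "spearman"):
        params = MeritParams(correlation=method)
        fast = MeritEngine(X, c, params, precompute=True)
        slow = MeritEngine(X, c, params, precompute=False)
        for _ in range(20):
            idx = np.flatnonzero(rng.random(12) < 0.4)
            assert fast.dcfs(idx) == pytest.approx(slow.dcfs(idx), abs=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        MeritParams(alpha=1.5)
    with pytest.raises(ValueError):
        MeritParams(correlation="kendall")
    with pytest.raises(ValueError):
        MeritParams(negative_correlation_policy="flip")
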