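"""CFS and DCFS merit functions over feature-selection masks.

The correlation-based feature selection (CFS) merit of a subset of n
features is

    M_CFS = n * rbar_fc / sqrt(n + n*(n-1) * rbar_ff)

where rbar_fc is the mean feature-class correlation over the selected
features and rbar_ff the mean absolute feature-feature correlation over
all selected pairs. The numerator rewards class association; the
denominator penalizes redundancy among the selected features.

The dual variant (DCFS) scores a subset against both class indicators at
once via linear scalarization:

    M_DCFS = alpha * M_p + (1 - alpha) * M_n

with M_p and M_n CFS-shaped merits against the positive and negative
class indicators c^p and c^n, sharing one rbar_ff. alpha in [0, 1]
trades the two objectives; alpha=1 recovers plain CFS against c^p,
alpha=0 against c^n, and alpha=0.5 weighs both classes equally so that
features tied to either class can be selected without redundancy.

Because c^n = 1 - c^p, the signed Pearson correlations satisfy
rho(e, c^n) = -rho(e, c^p) exactly, and a signed reading of the dual
merit at alpha=0.5 would vanish identically. A feature is meant to
contribute to M_p *or* M_n — it is associated with one class — so the
default ``negative_correlation_policy`` clips negative feature-class
correlations to zero. ``absolute`` and ``signed`` are available for
sensitivity analysis. Feature-feature correlations always enter as
absolute values (otherwise the denominator's square root can be fed a
negative number); this matches the standard CFS formulation.

Degenerate subsets are defined by the merit's algebra: the empty subset
has merit 0, and a singleton's merit is its (transformed) feature-class
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import VALID_METHODS, column_correlations, feature_class_correlations
from .matrix import FeatureMatrix

VALID_POLICIES = ("clip_to_zero", "absolute", "signed")


@dataclass(frozen=True)
class MeritParams:
    """Knobs shared by every merit computation.

    alpha : scalarization weight in [0, 1] (dual merit only).
    correlation : "pearson" or "spearman".
    negative_correlation_policy : transform applied to feature-class
        correlations before averaging; one of "clip_to_zero" (default),
        "absolute", "signed".
    """

    alpha: float = 0.5
    correlation: str = "pearson"
    negative_correlation_policy: str = "clip_to_zero"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.correlation not in VALID_METHODS:
            raise ValueError(f"correlation must be one of {VALID_METHODS}")
        if self.negative_correlation_policy not in VALID_POLICIES:
            raise ValueError(f"negative_correlation_policy must be one of {VALID_POLICIES}")


def _apply_policy(r: np.ndarray, policy: str) -> np.ndarray:
    if policy == "clip_to_zero":
        return np.maximum(r, 0.0)
    if policy == "absolute":
        return np.abs(r)
    return r


def merit_from_means(n: int, r_fc: float, r_ff: float) -> float:
    """The CFS merit formula from its three summary quantities."""
    if n == 0:
        return 0.0
    return float(n * r_fc / np.sqrt(n + n * (n - 1) * r_ff))


def _coerce(E, c=None):
    """Accept a FeatureMatrix or a plain array (+ explicit class vector)."""
    if isinstance(E, FeatureMatrix):
        return E.X, E.c_pos
    return np.asarray(E, dtype=float), (None if c is None else np.asarray(c))


class MeritEngine:
    """Precomputed correlation state for repeated merit evaluation.

    Both the Monte-Carlo weighting loop and the BPSO swarm evaluate the
    merit of thousands of subsets of one fixed matrix; each evaluation
    then only needs means over precomputed per-feature and per-pair
    correlations. For matrices too wide to hold a V x V block
    (``precompute=False`` or V above the auto threshold), pair
    correlations are computed per subset instead — identical values,
    just slower per call.
    """

    _AUTO_PRECOMPUTE_MAX = 4096

    def __init__(self, X, c_pos, params: MeritParams | None = None, precompute: bool | None = None):
        self.params = params or MeritParams()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.c_pos = np.asarray(c_pos, dtype=float)
        if self.c_pos.shape != (self.X.shape[0],):
            raise ValueError("c_pos length must equal the number of samples")
        method = self.params.correlation
        c_neg = 1.0 - self.c_pos
        raw_pos = feature_class_correlations(self.X, self.c_pos, method=method)
        raw_neg = feature_class_correlations(self.X, c_neg, method=method)
        policy = self.params.negative_correlation_policy
        self.fc_pos = _apply_policy(raw_pos, policy)
        self.fc_neg = _apply_policy(raw_neg, policy)
        if precompute is None:
            precompute = self.X.shape[1] <= self._AUTO_PRECOMPUTE_MAX
        self._ff = np.abs(column_correlations(self.X, method=method)) if precompute else None

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def mean_feature_feature(self, idx: np.ndarray) -> float:
        """Mean absolute correlation over all selected pairs i != j."""
        idx = np.asarray(idx, dtype=int)
        n = idx.size
        if n < 2:
            return 0.0
        if self._ff is not None:
            sub = self._ff[np.ix_(idx, idx)]
        else:
            sub = np.abs(column_correlations(self.X[:, idx], method=self.params.correlation))
        return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))

    def _single(self, idx: np.ndarray, fc: np.ndarray, r_ff: float) -> float:
        n = idx.size
        if n == 0:
            return 0.0
        return merit_from_means(n, float(fc[idx].mean()), r_ff)

    def cfs(self, idx, target: str = "positive") -> float:
        """CFS merit of the subset ``idx`` against one class indicator."""
        idx = np.asarray(idx, dtype=int)
        fc = self.fc_pos if target == "positive" else self.fc_neg
        return self._single(idx, fc, self.mean_feature_feature(idx))

    def dcfs(self, idx) -> float:
        """Dual merit alpha*M_p + (1-alpha)*M_n of the subset ``idx``."""
        idx = np.asarray(idx, dtype=int)
        r_ff = self.mean_feature_feature(idx)
        alpha = self.params.alpha
        m_p = self._single(idx, self.fc_pos, r_ff)
        m_n = self._single(idx, self.fc_neg, r_ff)
        return alpha * m_p + (1.0 - alpha) * m_n


def _mask_to_idx(x, n_features: int) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype == bool or set(np.unique(x)).issubset({0, 1}):
        if x.size != n_features:
            raise ValueError("selection mask length must equal the number of features")
        return np.flatnonzero(x)
    raise ValueError("selection mask must be binary")


def mean_feature_feature_corr(E, x, method: str = "pearson") -> float:
    """Mean absolute pairwise correlation among the selected features."""
    X, _ = _coerce(E)
    idx = _mask_to_idx(x, X.shape[1])
    eng = MeritEngine(X, np.zeros(X.shape[0]), MeritParams(correlation=method), precompute=False)
    return eng.mean_feature_feature(idx)


def mean_feature_class_corr(E, x, c=None, params: MeritParams | None = None) -> float:
    """Mean policy-transformed correlation of selected features with ``c``."""
    params = params or MeritParams()
    X, c_auto = _coerce(E, c)
    c = c if c is not None else c_auto
    if c is None:
        raise ValueError("a class indicator vector is required")
    idx = _mask_to_idx(x, X.shape[1])
    if idx.size == 0:
        return 0.0
    raw = feature_class_correlations(X[:, idx], np.asarray(c, float), method=params.correlation)
    return float(_apply_policy(raw, params.negative_correlation_policy).mean())


def cfs_merit(E, x, c=None, params: MeritParams | None = None) -> float:
    """CFS merit of mask ``x`` against class vector ``c``."""
    params = params or MeritParams()
    X, c_auto = _coerce(E, c)
    c = c if c is not None else c_auto
    if c is None:
        raise ValueError("a class indicator vector is required")
    idx = _mask_to_idx(x, X.shape[1])
    eng = MeritEngine(X, np.asarray(c, float), params, precompute=False)
    return eng.cfs(idx, target="positive")


def dcfs_merit(E, x, c_pos=None, params: MeritParams | None = None) -> float:
    """Dual merit of mask ``x``; ``E`` may carry c^p or it is given explicitly."""
    params = params or MeritParams()
    X, cp = _coerce(E, c_pos)
    cp = c_pos if c_pos is not None else cp
    if cp is None:
        raise ValueError("a positive-class indicator vector is required")
    idx = _mask_to_idx(x, X.shape[1])
    eng = MeritEngine(X, np.asarray(cp, float), params, precompute=False)
    return eng.dcfs(idx)


__all__ = [
    "MeritParams",
    "MeritEngine",
    "merit_from_means",
    "mean_feature_feature_corr",
    "mean_feature_class_corr",
    "cfs_merit",
    "dcfs_merit",
    "VALID_POLICIES",
]
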