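"""Monte-Carlo DCFS weighting: per-feature importance by random subsets.

Searching all 2^V - 1 subsets for the merit optimum is hopeless at
genomic dimensionality, so each feature's importance is estimated as the
average dual merit of random subsets containing it. For T1 iterations a
subset size phi is drawn uniformly from the admissible set Phi, phi
distinct features are drawn uniformly without replacement, the dual
merit of that submatrix is computed, added to the w_val accumulator of
every drawn feature, and each such feature's w_num count is incremented.
The weight vector is w = w_val / w_num, and the top D1 features by
weight become the candidate set for the subsequent subset optimization.

Features that were never sampled (w_num = 0) have an *unknown* — not
zero — weight; they are excluded from the top-D1 ranking, and asking for
more candidates than were ever sampled is an error advising a larger T1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .merit import MeritEngine, MeritParams

logger = logging.getLogger(__name__)

DEFAULT_PHI = range(2, 101)
DEFAULT_T1 = 10**6


@dataclass
class WeightingResult:
    """Accumulators and derived weights of one weighting run.

    ``weights`` is NaN wherever ``w_num`` is 0 (feature never sampled).
    """

    w_val: np.ndarray
    w_num: np.ndarray
    phi_set: tuple[int, ...]
    n_iterations: int
    seed: int | None
    params: MeritParams = field(default_factory=MeritParams)

    @property
    def weights(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            w = self.w_val / self.w_num
        w[self.w_num == 0] = np.nan
        return w

    @property
    def n_sampled(self) -> int:
        return int((self.w_num > 0).sum())

    def to_frame(self, feature_ids=None) -> pd.DataFrame:
        """Weights table sorted by weight descending (ties: input order)."""
        v = self.w_val.size
        ids = list(feature_ids) if feature_ids is not None else [str(i) for i in range(v)]
        df = pd.DataFrame(
            {"feature_id": ids, "w_val": self.w_val, "w_num": self.w_num, "w": self.weights}
        )
        order = np.argsort(-np.nan_to_num(self.weights, nan=-np.inf), kind="stable")
        return df.iloc[order].reset_index(drop=True)


def run_weighting(
    X,
    c_pos,
    params: MeritParams | None = None,
    phi_set=DEFAULT_PHI,
    n_iterations: int = DEFAULT_T1,
    seed: int | None = 0,
    engine: MeritEngine | None = None,
) -> WeightingResult:
    """Estimate DCFS weights for every feature of ``X``.

    A single seeded RNG stream drives both the subset-size draw and the
    feature draw of each iteration, in that order, so runs are exactly
    reproducible from the seed.
    """
    params = params or MeritParams()
    if engine is None:
        engine = MeritEngine(X, c_pos, params)
    else:
        params = engine.params
    n_features = engine.n_features
    phi = np.unique(np.asarray(list(phi_set), dtype=int))
    if phi.size == 0:
        raise ValueError("phi_set must be non-empty")
    if phi.min() < 2:
        raise ValueError("subset sizes must be >= 2")
    if phi.max() > n_features:
        raise ValueError(
            f"largest subset size {phi.max()} exceeds the {n_features} available features"
        )
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    w_val = np.zeros(n_features)
    w_num = np.zeros(n_features, dtype=np.int64)
    for _ in range(n_iterations):
        size = int(phi[rng.integers(phi.size)])
        idx = rng.choice(n_features, size=size, replace=False)
        m = engine.dcfs(idx)
        w_val[idx] += m
        w_num[idx] += 1
    return WeightingResult(
        w_val=w_val,
        w_num=w_num,
        phi_set=tuple(int(p) for p in phi),
        n_iterations=n_iterations,
        seed=seed,
        params=params,
    )


def select_top(weights, d1: int, w_num=None) -> np.ndarray:
    """Indices of the ``d1`` largest weights, descending; ties broken by
    ascending feature index. NaN weights (never-sampled features) are
    excluded from the ranking."""
    w = np.asarray(weights, dtype=float)
    if w_num is not None:
        w = w.copy()
        w[np.asarray(w_num) == 0] = np.nan
    defined = np.flatnonzero(~np.isnan(w))
    if d1 < 1:
        raise ValueError("d1 must be >= 1")
    if defined.size < d1:
        raise ValueError(
            f"only {defined.size} features have defined weights but d1={d1}; "
            "increase the number of weighting iterations (T1)"
        )
    order = defined[np.argsort(-w[defined], kind="stable")]
    return order[:d1]


__all__ = ["WeightingResult", "run_weighting", "select_top", "DEFAULT_PHI", "DEFAULT_T1"]
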