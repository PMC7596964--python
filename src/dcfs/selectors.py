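"""Scikit-learn estimators wrapping the two-stage selection protocol.

:class:`DCFSWeightingSelector` is the Monte-Carlo weighting stage (keep
the top D1 features by dual-merit weight); :class:`BPSOSelector` is the
swarm-search stage (find the merit- or CV-F1-optimal subset of the
columns it is fit on); :class:`DualCorrelationFeatureSelector` chains
the two, so that ``fit(X, y).transform(X)`` goes straight from the full
matrix to the final D2 columns. All three are SelectorMixin
transformers and compose with sklearn pipelines and model selection.

``y`` is any binary label vector; the *larger* label value is taken as
the positive class (the sklearn convention), overridable via
``pos_label``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .bpso import BPSOParams, bpso_optimize, cv_f1_fitness, merit_fitness
from .merit import MeritParams
from .weighting import run_weighting, select_top


def _binary_indicator(y, pos_label=None):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"binary labels required, got classes {classes!r}")
    positive = classes.max() if pos_label is None else pos_label
    if positive not in classes:
        raise ValueError(f"pos_label {positive!r} not among classes {classes!r}")
    return (y == positive).astype(int), classes


class _MeritParamsMixin:
    def _merit_params(self) -> MeritParams:
        return MeritParams(
            alpha=self.alpha,
            correlation=self.correlation,
            negative_correlation_policy=self.negative_correlation_policy,
        )


class DCFSWeightingSelector(_MeritParamsMixin, SelectorMixin, BaseEstimator):
    """Select the top ``d1`` features by Monte-Carlo dual-merit weight.

    Parameters
    ----------
    d1 : number of candidate features to keep.
    alpha : scalarization weight; 1.0 gives plain CFS against the
        positive class, 0.0 against the negative, 0.5 weighs both.
    correlation : "pearson" or "spearman".
    negative_correlation_policy : "clip_to_zero", "absolute" or "signed".
    phi_min, phi_max : inclusive bounds of the random subset size.
    n_iterations : Monte-Carlo iterations T1.
    pos_label : which label is the positive class (default: the larger).
    random_state : seed of the single RNG stream.

    Attributes
    ----------
    weights_ : per-feature weight (NaN where never sampled).
    w_val_, w_num_ : the raw accumulators behind ``weights_``.
    support_ : boolean mask of the selected features.
    ranking_ : selected feature indices, best first.
    """

    def __init__(
        self,
        d1: int = 50,
        alpha: float = 0.5,
        correlation: str = "pearson",
        negative_correlation_policy: str = "clip_to_zero",
        phi_min: int = 2,
        phi_max: int = 100,
        n_iterations: int = 10**6,
        pos_label=None,
        random_state: int | None = 0,
    ):
        self.d1 = d1
        self.alpha = alpha
        self.correlation = correlation
        self.negative_correlation_policy = negative_correlation_policy
        self.phi_min = phi_min
        self.phi_max = phi_max
        self.n_iterations = n_iterations
        self.pos_label = pos_label
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        c_pos, self.classes_ = _binary_indicator(y, self.pos_label)
        phi_max = min(self.phi_max, X.shape[1])
        result = run_weighting(
            X,
            c_pos,
            params=self._merit_params(),
            phi_set=range(self.phi_min, phi_max + 1),
            n_iterations=self.n_iterations,
            seed=self.random_state,
        )
        self.weighting_result_ = result
        self.w_val_ = result.w_val
        self.w_num_ = result.w_num
        self.weights_ = result.weights
        self.ranking_ = select_top(self.weights_, self.d1)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class BPSOSelector(_MeritParamsMixin, SelectorMixin, BaseEstimator):
    """Find the fitness-optimal feature subset of X with a binary swarm.

    ``fitness="merit"`` maximizes the dual merit directly (the filter
    reading of the protocol); ``fitness="cv_f1"`` maximizes mean F1 of a
    classifier under stratified k-fold cross-validation (the wrapper
    reading used for the headline comparisons).

    Attributes
    ----------
    support_ : boolean mask (the global-best position).
    n_selected_ : popcount of the global best (D2).
    best_fitness_ : fitness of the global best.
    """

    def __init__(
        self,
        fitness: str = "merit",
        alpha: float = 0.5,
        correlation: str = "pearson",
        negative_correlation_policy: str = "clip_to_zero",
        n_iterations: int = 100,
        n_particles: int = 100,
        inertia: float = 0.5,
        c1: float = 2.0,
        c2: float = 2.0,
        v_min: float = -6.0,
        v_max: float = 6.0,
        estimator=None,
        cv: int = 10,
        pos_label=None,
        random_state: int | None = 0,
    ):
        self.fitness = fitness
        self.alpha = alpha
        self.correlation = correlation
        self.negative_correlation_policy = negative_correlation_policy
        self.n_iterations = n_iterations
        self.n_particles = n_particles
        self.inertia = inertia
        self.c1 = c1
        self.c2 = c2
        self.v_min = v_min
        self.v_max = v_max
        self.estimator = estimator
        self.cv = cv
        self.pos_label = pos_label
        self.random_state = random_state

    def _bpso_params(self) -> BPSOParams:
        return BPSOParams(
            n_iterations=self.n_iterations,
            inertia=self.inertia,
            c1=self.c1,
            c2=self.c2,
            v_min=self.v_min,
            v_max=self.v_max,
            n_particles=self.n_particles,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        c_pos, self.classes_ = _binary_indicator(y, self.pos_label)
        if self.fitness == "merit":
            fn = merit_fitness(X, c_pos, self._merit_params())
        elif self.fitness == "cv_f1":
            fn = cv_f1_fitness(
                X, c_pos, estimator=self.estimator, k=self.cv, seed=self.random_state
            )
        else:
            raise ValueError("fitness must be 'merit' or 'cv_f1'")
        result = bpso_optimize(fn, X.shape[1], self._bpso_params(), seed=self.random_state)
        self.result_ = result
        self.support_ = result.mask
        self.n_selected_ = result.n_selected
        self.best_fitness_ = result.fitness
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class DualCorrelationFeatureSelector(_MeritParamsMixin, SelectorMixin, BaseEstimator):
    """The full two-stage protocol: weighting to D1, then swarm search to D2.

    Attributes
    ----------
    weighting_ : the fitted stage-1 :class:`DCFSWeightingSelector`.
    bpso_ : the fitted stage-2 :class:`BPSOSelector` (over the D1 columns).
    support_ : boolean mask over the *original* features (D2 of them set).
    n_selected_ : D2.
    """

    def __init__(
        self,
        d1: int = 50,
        alpha: float = 0.5,
        correlation: str = "pearson",
        negative_correlation_policy: str = "clip_to_zero",
        phi_min: int = 2,
        phi_max: int = 100,
        t1: int = 10**6,
        t2: int = 100,
        n_particles: int = 100,
        inertia: float = 0.5,
        c1: float = 2.0,
        c2: float = 2.0,
        v_min: float = -6.0,
        v_max: float = 6.0,
        fitness: str = "cv_f1",
        estimator=None,
        cv: int = 10,
        pos_label=None,
        random_state: int | None = 0,
    ):
        self.d1 = d1
        self.alpha = alpha
        self.correlation = correlation
        self.negative_correlation_policy = negative_correlation_policy
        self.phi_min = phi_min
        self.phi_max = phi_max
        self.t1 = t1
        self.t2 = t2
        self.n_particles = n_particles
        self.inertia = inertia
        self.c1 = c1
        self.c2 = c2
        self.v_min = v_min
        self.v_max = v_max
        self.fitness = fitness
        self.estimator = estimator
        self.cv = cv
        self.pos_label = pos_label
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.weighting_ = DCFSWeightingSelector(
            d1=self.d1,
            alpha=self.alpha,
            correlation=self.correlation,
            negative_correlation_policy=self.negative_correlation_policy,
            phi_min=self.phi_min,
            phi_max=self.phi_max,
            n_iterations=self.t1,
            pos_label=self.pos_label,
            random_state=self.random_state,
        ).fit(X, y)
        d1_idx = self.weighting_.ranking_
        self.bpso_ = BPSOSelector(
            fitness=self.fitness,
            alpha=self.alpha,
            correlation=self.correlation,
            negative_correlation_policy=self.negative_correlation_policy,
            n_iterations=self.t2,
            n_particles=self.n_particles,
            inertia=self.inertia,
            c1=self.c1,
            c2=self.c2,
            v_min=self.v_min,
            v_max=self.v_max,
            estimator=self.estimator,
            cv=self.cv,
            pos_label=self.pos_label,
            random_state=self.random_state,
        ).fit(X[:, d1_idx], y)
        self.classes_ = self.weighting_.classes_
        self.d1_indices_ = d1_idx
        self.d2_indices_ = d1_idx[self.bpso_.support_]
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.d2_indices_] = True
        self.n_selected_ = int(self.support_.sum())
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


__all__ = ["DCFSWeightingSelector", "BPSOSelector", "DualCorrelationFeatureSelector"]
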