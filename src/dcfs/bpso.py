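"""Binary particle swarm optimization over feature-selection masks.

Each of P particles carries a binary position x (a candidate feature
subset over the D1 pre-selected features) and a real velocity v. Per
iteration and dimension,

    v <- a*v + c1*r1*(pb - x) + c2*r2*(gb - x),   v clamped to [v_min, v_max]
    x <- 1 if rand < sigmoid(v) else 0

with r1, r2, rand ~ U[0,1], pb the particle's personal best and gb the
swarm's global best. Personal and global bests update on *strict*
fitness improvement (ties keep the incumbent), so the global-best
fitness trace is non-decreasing. After T2 iterations the global best is
the selected subset; its popcount is D2.

Randomness comes from one seeded Generator; per iteration the draw
order is r1, then r2, then the position threshold, each as a (P, D)
block in particle-major/dimension-minor (C) order, which makes runs
bit-reproducible. Positions initialize i.i.d. Bernoulli(0.5) and
velocities uniform on [v_min, v_max].

The fitness is any total function of the mask; empty-mask handling is
the fitness's job (both fitness factories here return 0 for it).
Fitness values are memoized by mask, which is transparent because the
fitness is required to be pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.svm import SVC

from .merit import MeritEngine, MeritParams


@dataclass(frozen=True)
class BPSOParams:
    """Swarm hyperparameters: T2 iterations, inertia a, accelerations
    c1/c2, velocity clamp, particle count, in their conventional units."""

    n_iterations: int = 100
    inertia: float = 0.5
    c1: float = 2.0
    c2: float = 2.0
    v_min: float = -6.0
    v_max: float = 6.0
    n_particles: int = 100

    def __post_init__(self) -> None:
        if self.v_min >= self.v_max:
            raise ValueError("v_min must be < v_max")
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")


@dataclass
class Swarm:
    x: np.ndarray          # (P, D) int8 positions
    v: np.ndarray          # (P, D) velocities
    pb: np.ndarray         # (P, D) personal-best positions
    pb_fitness: np.ndarray  # (P,)
    gb: np.ndarray         # (D,) global-best position
    gb_fitness: float
    t: int = 0


@dataclass
class BPSOResult:
    mask: np.ndarray
    fitness: float
    n_selected: int
    n_evaluations: int
    history: list[float] = field(repr=False, default_factory=list)


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def _memoized(fitness):
    cache: dict[bytes, float] = {}

    def f(row: np.ndarray) -> float:
        key = row.tobytes()
        if key not in cache:
            cache[key] = float(fitness(row.astype(bool)))
        return cache[key]

    f.cache = cache  # type: ignore[attr-defined]
    return f


def init_swarm(fitness, n_dims: int, params: BPSOParams, rng: np.random.Generator) -> Swarm:
    """Random swarm; the initial global best is the best initial particle."""
    p = params.n_particles
    x = (rng.random((p, n_dims)) < 0.5).astype(np.int8)
    v = rng.uniform(params.v_min, params.v_max, size=(p, n_dims))
    fit = np.array([fitness(x[i]) for i in range(p)])
    best = int(np.argmax(fit))
    return Swarm(
        x=x,
        v=v,
        pb=x.copy(),
        pb_fitness=fit,
        gb=x[best].copy(),
        gb_fitness=float(fit[best]),
    )


def bpso_step(swarm: Swarm, fitness, params: BPSOParams, rng: np.random.Generator) -> Swarm:
    """One synchronous update of every particle, in place."""
    p, d = swarm.x.shape
    r1 = rng.random((p, d))
    r2 = rng.random((p, d))
    thresh = rng.random((p, d))
    swarm.v = (
        params.inertia * swarm.v
        + params.c1 * r1 * (swarm.pb - swarm.x)
        + params.c2 * r2 * (swarm.gb[None, :] - swarm.x)
    )
    np.clip(swarm.v, params.v_min, params.v_max, out=swarm.v)
    swarm.x = (thresh < sigmoid(swarm.v)).astype(np.int8)
    fit = np.array([fitness(swarm.x[i]) for i in range(p)])
    improved = fit > swarm.pb_fitness
    swarm.pb[improved] = swarm.x[improved]
    swarm.pb_fitness[improved] = fit[improved]
    best = int(np.argmax(swarm.pb_fitness))
    if swarm.pb_fitness[best] > swarm.gb_fitness:
        swarm.gb = swarm.pb[best].copy()
        swarm.gb_fitness = float(swarm.pb_fitness[best])
    swarm.t += 1
    return swarm


def bpso_optimize(
    fitness,
    n_dims: int,
    params: BPSOParams | None = None,
    seed: int | None = 0,
) -> BPSOResult:
    """Run the swarm for T2 iterations and return the global best mask."""
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    params = params or BPSOParams()
    rng = np.random.default_rng(seed)
    f = _memoized(fitness)
    swarm = init_swarm(f, n_dims, params, rng)
    history = [swarm.gb_fitness]
    for _ in range(params.n_iterations):
        bpso_step(swarm, f, params, rng)
        history.append(swarm.gb_fitness)
    mask = swarm.gb.astype(bool)
    return BPSOResult(
        mask=mask,
        fitness=swarm.gb_fitness,
        n_selected=int(mask.sum()),
        n_evaluations=len(f.cache),
        history=history,
    )


def exhaustive_search(fitness, n_dims: int, include_empty: bool = False):
    """Brute-force optimum over all 2^D - 1 non-empty masks (oracle-scale
    only). Ties resolve to the first mask in enumeration order."""
    if n_dims > 20:
        raise ValueError("exhaustive search is limited to <= 20 dimensions")
    best_mask, best_fit = None, -np.inf
    start = 0 if include_empty else 1
    for bits in range(start, 2**n_dims):
        mask = np.array([(bits >> d) & 1 for d in range(n_dims)], dtype=bool)
        val = float(fitness(mask))
        if val > best_fit:
            best_mask, best_fit = mask, val
    return best_mask, best_fit


# ---- fitness factories ---------------------------------------------------


def merit_fitness(X, c_pos, params: MeritParams | None = None, engine: MeritEngine | None = None):
    """Fitness = dual merit of the masked submatrix."""
    engine = engine or MeritEngine(X, c_pos, params)

    def fitness(mask: np.ndarray) -> float:
        return engine.dcfs(np.flatnonzero(mask))

    return fitness


def cv_f1_fitness(X, y, estimator=None, k: int = 10, seed: int | None = 0, stratified: bool = True):
    """Fitness = mean F1 over k-fold cross-validation on the masked columns.

    The fold assignment depends only on (y, seed), never on the mask, so
    every mask is scored on identical splits. The empty mask scores 0.
    """
    from .evaluate import kfold_cv  # local import: avoids a module cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    estimator = estimator if estimator is not None else SVC(kernel="linear")

    def fitness(mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return 0.0
        res = kfold_cv(X[:, idx], y, clone(estimator), k=k, seed=seed, stratified=stratified)
        return res.mean_f1

    return fitness


__all__ = [
    "BPSOParams",
    "Swarm",
    "BPSOResult",
    "sigmoid",
    "init_swarm",
    "bpso_step",
    "bpso_optimize",
    "exhaustive_search",
    "merit_fitness",
    "cv_f1_fitness",
]
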