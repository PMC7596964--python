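"""Pearson and Spearman correlation engines.

These back every merit computation in the package. Two conventions are
load-bearing for sparse binary variant matrices and are therefore fixed
here rather than delegated to :func:`numpy.corrcoef`:

* a vector with zero variance has correlation 0 with anything (a constant
  feature carries no class information; ``np.corrcoef`` would return NaN);
* tied values receive average ranks (the standard Spearman convention,
  essential because 0/1 carrier columns are tie-heavy).

Spearman correlation is, by definition here, the Pearson correlation of
the rank-transformed vectors — the identity holds exactly, ties included.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

VALID_METHODS = ("pearson", "spearman")


def _check_method(method: str) -> str:
    if method not in VALID_METHODS:
        raise ValueError(f"unknown correlation method {method!r}; expected one of {VALID_METHODS}")
    return method


def rank_transform(a) -> np.ndarray:
    """Ranks 1..n of ``a``, ties receiving the average of their positions."""
    a = np.asarray(a, dtype=float)
    if a.size < 1:
        raise ValueError("rank_transform requires at least one element")
    return rankdata(a)


def pcc(a, b) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Returns 0.0 when either vector has zero variance. Result is clipped
    to [-1, 1] to absorb floating-point overshoot.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("pcc expects 1-D vectors")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.size < 2:
        raise ValueError("pcc requires vectors of length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt(ac @ ac)
    nb = np.sqrt(bc @ bc)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))


def scc(a, b) -> float:
    """Spearman rank correlation: ``pcc`` on average-rank-transformed inputs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return pcc(rank_transform(a), rank_transform(b))


def correlate(a, b, method: str = "pearson") -> float:
    """Dispatch to :func:`pcc` or :func:`scc` by method name."""
    _check_method(method)
    return pcc(a, b) if method == "pearson" else scc(a, b)


def _rank_columns(A: np.ndarray) -> np.ndarray:
    return rankdata(A, axis=0)


def column_correlations(A, B=None, method: str = "pearson") -> np.ndarray:
    """Correlation matrix between the columns of ``A`` and of ``B`` (or ``A``).

    Rows/columns corresponding to zero-variance input columns are 0,
    including the diagonal entry of a constant column correlated with
    itself.

    Parameters
    ----------
    A : (S, V1) array
    B : (S, V2) array, optional
    method : "pearson" or "spearman"

    Returns
    -------
    (V1, V2) array of correlations in [-1, 1].
    """
    _check_method(method)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.ndim != 2:
        raise ValueError("column_correlations expects a 2-D matrix")
    symmetric = B is None
    B = A if symmetric else np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] != A.shape[0]:
        raise ValueError("A and B must have the same number of rows (samples)")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if method == "spearman":
        A = _rank_columns(A)
        B = A if symmetric else _rank_columns(B)
    Ac = A - A.mean(axis=0)
    Bc = Ac if symmetric else B - B.mean(axis=0)
    na = np.sqrt(np.einsum("ij,ij->j", Ac, Ac))
    nb = na if symmetric else np.sqrt(np.einsum("ij,ij->j", Bc, Bc))
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Ac.T @ Bc) / denom
    C[na == 0.0, :] = 0.0
    C[:, nb == 0.0] = 0.0
    return np.clip(C, -1.0, 1.0)


def feature_class_correlations(A, c, method: str = "pearson") -> np.ndarray:
    """Correlation of every column of ``A`` with the class vector ``c``."""
    c = np.asarray(c, dtype=float)
    return column_correlations(A, c[:, None], method=method)[:, 0]
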