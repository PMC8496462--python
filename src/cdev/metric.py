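"""Condition-number based deviation (cdev) between expression matrices.

Given a normalized gene-by-sample matrix ``X`` and a ground-truth matrix
``A`` of the same shape, let ``B`` be the linear map with ``X B = A``.  A
normalization is considered perfect when ``B`` is a scalar multiple of the
identity, so the quality of ``X`` is scored by how far ``B`` deviates from
that form, measured by its 2-norm condition number::

    cdev(X, A) = kappa(X^+ A) = sigma_max(X^+ A) / sigma_min(X^+ A)

where ``X^+`` is the Moore-Penrose pseudoinverse.  cdev is 1 for a perfect
normalization and grows without bound as the per-sample scaling drifts
apart; it is symmetric whenever the transformation between the two
matrices is a pure column scaling.

Two computation routes are provided:

* :func:`cdev_general` — the defining SVD/pseudoinverse route, valid for
  any same-shape pair;
* :func:`cdev_diagonal` — an exact fast path when ``A`` is a column-scaled
  version of ``X``: the diagonal of ``B`` is recovered by dividing one
  all-positive gene row of ``A`` by the matching row of ``X``.

When both matrices are known scalings of the same raw count matrix,
:func:`cdev_from_factors` computes the same quantity in O(m) directly from
the two scaling vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ShapeMismatchError

logger = logging.getLogger(__name__)

#: Relative cutoff below which a singular value is treated as zero.
DEFAULT_SIGMA_TOL = 1e-12


@dataclass(frozen=True)
class CdevResult:
    """Outcome of a cdev computation.

    Attributes
    ----------
    value:
        The deviation, >= 1; ``numpy.inf`` when the transformation is
        numerically rank-deficient.
    sigma_max, sigma_min:
        Largest and smallest singular values of the transformation ``B``.
    path:
        ``"diagonal"`` (fast path) or ``"svd"`` (general path).
    scaling_ratios:
        Per-sample diagonal of ``B`` (diagonal path only), aligned to the
        sample order of the inputs.
    """

    value: float
    sigma_max: float
    sigma_min: float
    path: str
    scaling_ratios: np.ndarray | None = None

    def __float__(self) -> float:  # convenience: float(result)
        return float(self.value)


def _extract(X, name: str) -> tuple[np.ndarray, pd.Index | None, pd.Index | None]:
    if isinstance(X, pd.DataFrame):
        values = X.to_numpy(dtype=float)
        genes, samples = X.index, X.columns
    else:
        values = np.asarray(X, dtype=float)
        genes = samples = None
    if values.ndim != 2:
        raise ShapeMismatchError(f"{name} must be a 2-D gene-by-sample matrix")
    if values.shape[0] < 1 or values.shape[1] < 2:
        raise ShapeMismatchError(
            f"{name} needs at least 1 gene and 2 samples, got {values.shape}"
        )
    if np.any(values < 0):
        # cdev is defined on linear-scale (count-like) matrices; negative
        # entries are the signature of log-transformed input.
        raise DegenerateInputError(
            f"{name} contains negative entries; cdev requires linear-scale "
            "matrices (log-transformed input is not supported)"
        )
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError(f"{name} contains non-finite entries")
    return values, genes, samples


def _check_pair(X, A) -> tuple[np.ndarray, np.ndarray]:
    xv, xg, xs = _extract(X, "X")
    av, ag, as_ = _extract(A, "A")
    if xv.shape != av.shape:
        raise ShapeMismatchError(f"shape mismatch: X {xv.shape} vs A {av.shape}")
    if xg is not None and ag is not None:
        if not xg.equals(ag):
            raise ShapeMismatchError("gene IDs of X and A differ (order matters)")
        if not xs.equals(as_):
            raise ShapeMismatchError("sample IDs of X and A differ (order matters)")
    return xv, av


def cdev_general(X, A, sigma_tol: float = DEFAULT_SIGMA_TOL) -> CdevResult:
    """cdev via the defining pseudoinverse/SVD route.

    ``X^+`` is formed from the thin SVD of ``X`` with singular values below
    ``sigma_tol * sigma_max(X)`` dropped; the condition number of
    ``B = X^+ A`` is then the ratio of its extreme singular values.  If
    ``sigma_min(B) / sigma_max(B)`` falls below ``sigma_tol`` the result is
    reported as infinite rather than as an unstable huge number.
    """
    if sigma_tol <= 0:
        raise ValueError("sigma_tol must be positive")
    xv, av = _check_pair(X, A)
    U, s, Vt = np.linalg.svd(xv, full_matrices=False)
    if s[0] == 0:
        raise DegenerateInputError("X is all-zero; cdev undefined")
    keep = s > sigma_tol * s[0]
    pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
    B = pinv @ av
    sb = np.linalg.svd(B, compute_uv=False)
    sigma_max, sigma_min = float(sb[0]), float(sb[-1])
    if sigma_max == 0:
        raise DegenerateInputError("A is all-zero; cdev undefined")
    if sigma_min < sigma_tol * sigma_max:
        value = float(np.inf)
    else:
        value = sigma_max / sigma_min
    return CdevResult(value=value, sigma_max=sigma_max, sigma_min=sigma_min, path="svd")


def _eligible_rows(xv: np.ndarray, av: np.ndarray) -> np.ndarray:
    return np.flatnonzero((xv > 0).all(axis=1) & (av > 0).all(axis=1))


def cdev_diagonal(
    X,
    A,
    pivot_policy: str = "maximin",
    cross_check_tol: float = 1e-6,
    sigma_tol: float = DEFAULT_SIGMA_TOL,
) -> CdevResult:
    """cdev fast path assuming ``A`` is a column scaling of ``X``.

    The diagonal of ``B`` is read off as ``b_j = A[i, j] / X[i, j]`` for a
    pivot gene ``i`` that is strictly positive in every sample of both
    matrices.  ``pivot_policy`` selects that row: ``"maximin"`` (default)
    picks the eligible row whose smallest entry is largest, which is robust
    against low-count rows; ``"first"`` takes the first eligible row.  A
    second eligible row is used to verify the column-scaling assumption; on
    disagreement beyond ``cross_check_tol`` (relative) the computation
    falls back to :func:`cdev_general`.
    """
    if pivot_policy not in ("maximin", "first"):
        raise ValueError(f"unknown pivot_policy {pivot_policy!r}")
    xv, av = _check_pair(X, A)
    rows = _eligible_rows(xv, av)
    if rows.size == 0:
        logger.warning(
            "no gene row strictly positive in both matrices; "
            "falling back to the SVD path"
        )
        return cdev_general(X, A, sigma_tol=sigma_tol)
    if pivot_policy == "maximin":
        minima = np.minimum(xv[rows].min(axis=1), av[rows].min(axis=1))
        order = np.argsort(minima)[::-1]
        rows = rows[order]
    pivot = rows[0]
    b = av[pivot] / xv[pivot]
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise DegenerateInputError("pivot ratio vector contains zero or infinity")
    if rows.size > 1:
        b2 = av[rows[1]] / xv[rows[1]]
        if np.max(np.abs(b2 - b) / b) > cross_check_tol:
            logger.warning(
                "second pivot row disagrees with the first beyond %.1e; "
                "A is not a column scaling of X — falling back to the SVD path",
                cross_check_tol,
            )
            return cdev_general(X, A, sigma_tol=sigma_tol)
    else:
        logger.info("single eligible pivot row; column-scaling assumption unchecked")
    sigma_max, sigma_min = float(b.max()), float(b.min())
    return CdevResult(
        value=sigma_max / sigma_min,
        sigma_max=sigma_max,
        sigma_min=sigma_min,
        path="diagonal",
        scaling_ratios=b,
    )


def cdev(X, A, method: str = "auto", sigma_tol: float = DEFAULT_SIGMA_TOL) -> CdevResult:
    """Compute cdev(X, A), choosing the route automatically by default.

    ``method="auto"`` tries the exact diagonal fast path (which itself
    falls back to the SVD route when the column-scaling assumption fails);
    ``"diagonal"`` and ``"svd"`` force a route.
    """
    if method == "auto" or method == "diagonal":
        return cdev_diagonal(X, A, sigma_tol=sigma_tol)
    if method == "svd":
        return cdev_general(X, A, sigma_tol=sigma_tol)
    raise ValueError(f"unknown method {method!r}")


def cdev_from_factors(u, v) -> CdevResult:
    """Exact cdev between two scalings of the same raw matrix.

    If ``X = Y / diag(v)`` and ``A = Y / diag(u)`` (each sample divided by
    its factor), cdev reduces to the ratio range
    ``max_j(u_j/v_j) / min_j(u_j/v_j)`` — identical in both orientations.  This is the canonical O(m) route when comparing
    normalizations of one count matrix.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ShapeMismatchError(f"factor length mismatch: {u.size} vs {v.size}")
    if u.size < 1:
        raise ShapeMismatchError("empty factor vectors")
    for name, w in (("u", u), ("v", v)):
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise DegenerateInputError(f"factor vector {name} must be positive finite")
    r = u / v
    sigma_max, sigma_min = float(r.max()), float(r.min())
    return CdevResult(
        value=sigma_max / sigma_min,
        sigma_max=sigma_max,
        sigma_min=sigma_min,
        path="diagonal",
        scaling_ratios=r,
    )
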