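"""Per-sample scaling factors: reference scaling and six global normalizers.

All functions take a gene-by-sample count :class:`pandas.DataFrame` and
return a :class:`NormalizationResult` whose ``factors`` are standardized
to geometric mean 1 — any scalar multiple of a factor vector yields an
equivalent normalization, and standardizing keeps normalized counts on a
magnitude comparable to the raw ones.  Samples are normalized by
*division*: :func:`apply_factors` computes ``X[i, j] = Y[i, j] / v_j``.

Methods
-------
``reference_factors``
    Ground-truth scaling against a set of stably-expressed reference
    genes (simulated non-DE genes, or ERCC spike-ins): the factor of a
    sample is its reference count sum divided by the geometric mean of
    those sums, so that reference sums are exactly equalized.
``tc_factors`` / ``uq_factors``
    Total count and upper-quartile scaling.
``tmm_factors``
    Mean of ratios to a reference sample over genes surviving two-sided
    trimming on the log-ratio (M) and average-abundance (A) scales.
``deseq_factors``
    Median of ratios to a per-gene geometric-mean pseudo-reference.
``deges_tmm_factors``
    Differentially-expressed-gene elimination: TMM, remove genes an
    internal DE caller flags, re-TMM on the remainder.
``poissonseq_factors``
    Iterative Poisson log-linear goodness-of-fit filtering; factors are
    retained-set count proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .exceptions import (
    DegenerateInputError,
    DegenerateReferenceError,
    EmptyRetainedSetError,
    InsufficientGenesError,
    InsufficientOverlapError,
)

logger = logging.getLogger(__name__)

METHODS = ("reference", "tc", "uq", "tmm", "deseq", "deges_tmm", "poissonseq")


@dataclass
class NormalizationResult:
    """Scaling factors plus bookkeeping about how they were obtained."""

    factors: pd.Series
    method: str
    retained_genes: frozenset = field(default_factory=frozenset)
    iterations: int = 0
    converged: bool = True


def _check_counts(Y: pd.DataFrame) -> np.ndarray:
    if not isinstance(Y, pd.DataFrame):
        raise TypeError("count matrix must be a pandas DataFrame (genes x samples)")
    values = Y.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise DegenerateInputError("need a 2-D matrix with at least 2 samples")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise DegenerateInputError("counts must be non-negative and finite")
    return values


def _standardize(raw: np.ndarray, samples: pd.Index) -> pd.Series:
    """Scale a positive factor vector to geometric mean 1."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise DegenerateInputError("scaling factors must be positive and finite")
    return pd.Series(raw / gmean(raw), index=samples, name="factor")


def apply_factors(Y: pd.DataFrame, factors) -> pd.DataFrame:
    """Scale each sample by its factor: ``X[i, j] = Y[i, j] / v_j``."""
    values = _check_counts(Y)
    if isinstance(factors, NormalizationResult):
        factors = factors.factors
    if isinstance(factors, pd.Series):
        v = factors.reindex(Y.columns).to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise DegenerateInputError("factors missing for some samples")
    else:
        v = np.asarray(factors, dtype=float).ravel()
        if v.size != Y.shape[1]:
            raise DegenerateInputError(
                f"{v.size} factors for {Y.shape[1]} samples"
            )
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise DegenerateInputError("scaling factors must be positive and finite")
    return pd.DataFrame(values / v, index=Y.index, columns=Y.columns)


def reference_factors(Y: pd.DataFrame, references) -> NormalizationResult:
    """Ground-truth scaling against a reference gene set.

    The factor of sample j is the reference count sum of that sample
    divided by the geometric mean of all samples' reference sums::

        v_j = sum_{i in R} y_ij / (prod_k sum_{i in R} y_ik)^(1/m)

    so the factor vector has geometric mean exactly 1, and after scaling
    the reference sums are identical across samples.
    """
    _check_counts(Y)
    refs = pd.Index(list(references)).astype(str)
    if refs.empty:
        raise DegenerateReferenceError("empty reference set")
    missing = refs.difference(Y.index)
    if not missing.empty:
        raise DegenerateReferenceError(
            f"{len(missing)} reference IDs absent from the matrix "
            f"(e.g. {missing[0]!r})"
        )
    sums = Y.loc[refs].sum(axis=0).to_numpy(dtype=float)
    if np.any(sums <= 0):
        bad = Y.columns[sums <= 0].tolist()
        raise DegenerateReferenceError(
            f"reference count sum is zero in sample(s) {bad}"
        )
    return NormalizationResult(
        factors=_standardize(sums, Y.columns),
        method="reference",
        retained_genes=frozenset(refs),
    )


def tc_factors(Y: pd.DataFrame) -> NormalizationResult:
    """Total-count scaling: factors proportional to per-sample count sums."""
    values = _check_counts(Y)
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        raise DegenerateInputError("a sample has zero total count")
    return NormalizationResult(
        factors=_standardize(totals, Y.columns),
        method="tc",
        retained_genes=frozenset(Y.index),
    )


def uq_factors(Y: pd.DataFrame) -> NormalizationResult:
    """Upper-quartile scaling over genes detected in at least one sample.

    The 75th percentile uses linear interpolation between order statistics
    (numpy's default), fixed here so results are reproducible across
    implementations.
    """
    values = _check_counts(Y)
    detected = values.sum(axis=1) > 0
    if not detected.any():
        raise DegenerateInputError("matrix is all-zero")
    uq = np.percentile(values[detected], 75, axis=0)
    if np.any(uq <= 0):
        bad = Y.columns[uq <= 0].tolist()
        raise DegenerateInputError(f"zero upper quartile in sample(s) {bad}")
    return NormalizationResult(
        factors=_standardize(uq, Y.columns),
        method="uq",
        retained_genes=frozenset(Y.index[detected]),
    )


def deseq_factors(Y: pd.DataFrame) -> NormalizationResult:
    """Median-of-ratios scaling against a geometric-mean pseudo-reference.

    Genes with a zero count in any sample are excluded (their geometric
    mean vanishes); the factor of sample j is the median over remaining
    genes of ``y_ij / (prod_k y_ik)^(1/m)``.
    """
    values = _check_counts(Y)
    allpos = (values > 0).all(axis=1)
    if not allpos.any():
        raise DegenerateInputError("no gene has positive counts in every sample")
    sub = values[allpos]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / geo[:, None]
    med = np.median(ratios, axis=0)
    return NormalizationResult(
        factors=_standardize(med, Y.columns),
        method="deseq",
        retained_genes=frozenset(Y.index[allpos]),
    )


def _trim_keep(values: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask keeping entries after symmetric rank trimming."""
    n = values.size
    cut = int(np.floor(frac * n))
    keep = np.zeros(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    keep[order[cut : n - cut]] = True
    return keep


def _tmm_raw_factors(
    values: np.ndarray,
    trim_m: float,
    trim_a: float,
    ref_sample: int,
    min_overlap: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-of-ratios TMM factors; returns (factors, union retained mask)."""
    n, m = values.shape
    ref = values[:, ref_sample]
    factors = np.ones(m)
    retained_union = np.zeros(n, dtype=bool)
    for j in range(m):
        if j == ref_sample:
            continue
        shared = (values[:, j] > 0) & (ref > 0)
        if shared.sum() < min_overlap:
            raise InsufficientOverlapError(
                f"only {int(shared.sum())} genes positive in both sample "
                f"{j} and the reference sample (need >= {min_overlap})"
            )
        yj, yr = values[shared, j], ref[shared]
        M = np.log2(yj / yr)
        A = 0.5 * np.log2(yj * yr)
        keep = _trim_keep(M, trim_m) & _trim_keep(A, trim_a)
        if not keep.any():
            raise InsufficientOverlapError(
                f"trimming removed every shared gene for sample {j}"
            )
        factors[j] = np.mean(yj[keep] / yr[keep])
        idx = np.flatnonzero(shared)[keep]
        retained_union[idx] = True
    return factors, retained_union


def tmm_factors(
    Y: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: int = 0,
) -> NormalizationResult:
    """Trimmed mean-of-ratios scaling against a reference sample.

    For each sample the genes positive in both it and the reference sample
    (``ref_sample``, 0-based, default the first) are ranked by log-ratio
    M = log2(y_j/y_ref) and abundance A = 0.5*log2(y_j*y_ref); the top and
    bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A are
    discarded, and the factor is the plain mean of count ratios over the
    survivors.  ``retained_genes`` is the union of per-sample surviving
    sets (trimming is sample-specific by construction).
    """
    values = _check_counts(Y)
    factors, retained = _tmm_raw_factors(values, trim_m, trim_a, ref_sample)
    return NormalizationResult(
        factors=_standardize(factors, Y.columns),
        method="tmm",
        retained_genes=frozenset(Y.index[retained]),
    )


def deges_tmm_factors(
    Y: pd.DataFrame,
    conditions,
    n_iter: int = 1,
    fdr: float = 0.10,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: int = 0,
) -> NormalizationResult:
    """DEGES with TMM as the normalizer and the internal DE caller.

    Iteration 0 is plain TMM on all genes.  Each subsequent iteration
    normalizes the counts with the current factors, calls differential
    genes on log-CPM at Benjamini-Hochberg FDR < ``fdr``, removes them,
    and recomputes the TMM factors restricted to the remaining (putatively
    non-differential) genes.  With the default single iteration this is
    the TMM -> DE -> TMM workflow.
    """
    from .evaluate import de_test, log_cpm  # local import: avoids a cycle

    _check_counts(Y)
    result = tmm_factors(Y, trim_m=trim_m, trim_a=trim_a, ref_sample=ref_sample)
    factors = result.factors
    retained = frozenset(Y.index)
    converged = False
    iterations = 0
    for _ in range(n_iter):
        de = de_test(log_cpm(Y, factors), conditions, fdr=fdr)
        keep = Y.index[~de.call.to_numpy()]
        if keep.empty:
            raise EmptyRetainedSetError("every gene was called differential")
        sub = tmm_factors(
            Y.loc[keep], trim_m=trim_m, trim_a=trim_a, ref_sample=ref_sample
        )
        iterations += 1
        change = np.max(np.abs(sub.factors - factors) / factors)
        factors = sub.factors
        retained = frozenset(keep)
        if change < 1e-8:
            converged = True
            break
    logger.info(
        "DEGES/TMM kept %d/%d genes after %d iteration(s)",
        len(retained), Y.shape[0], iterations,
    )
    return NormalizationResult(
        factors=factors,
        method="deges_tmm",
        retained_genes=retained,
        iterations=iterations,
        converged=converged,
    )


def poissonseq_factors(
    Y: pd.DataFrame,
    keep_quantiles: tuple[float, float] = (0.25, 0.75),
    max_iter: int = 20,
    tol: float = 1e-8,
    min_genes: int = 50,
) -> NormalizationResult:
    """Iterative Poisson goodness-of-fit scaling.

    Under the null that no gene is differential, counts follow
    ``y_ij ~ Poisson(v_j * d_i)`` with ``d_i`` the gene total and ``v_j``
    the sample's share of reads among the retained genes
    (``v_j = sum_{i in G} y_ij / sum_k sum_{i in G} y_ik``).  Each
    iteration scores every gene by its chi-squared goodness of fit
    ``GOF_i = sum_j (y_ij - yhat_ij)^2 / yhat_ij`` and retains the genes
    whose GOF lies inside the central ``keep_quantiles`` band — the
    best-conforming middle of the distribution.  Iteration stops when the
    retained set is stable or factors move less than ``tol``
    (max-relative); hitting ``max_iter`` flags ``converged=False``.
    """
    values = _check_counts(Y)
    lo_q, hi_q = keep_quantiles
    if not 0 <= lo_q < hi_q <= 1:
        raise ValueError("keep_quantiles must satisfy 0 <= lo < hi <= 1")
    totals = values.sum(axis=1)
    usable = totals > 0
    if usable.sum() < min_genes:
        raise InsufficientGenesError("too few genes with nonzero totals")
    retained = usable.copy()
    v_prev = None
    converged = False
    iterations = 0
    for _ in range(max_iter):
        colsum = values[retained].sum(axis=0)
        if np.any(colsum <= 0):
            raise InsufficientGenesError("retained set empty in some sample")
        v = colsum / colsum.sum()
        yhat = np.outer(totals[usable], v)
        gof = np.full(values.shape[0], np.inf)
        gof[usable] = ((values[usable] - yhat) ** 2 / yhat).sum(axis=1)
        finite = gof[usable]
        lo, hi = np.quantile(finite, [lo_q, hi_q])
        new_retained = usable & (gof >= lo) & (gof <= hi)
        if new_retained.sum() < min_genes:
            raise InsufficientGenesError(
                f"retained set shrank to {int(new_retained.sum())} genes "
                f"(minimum {min_genes})"
            )
        iterations += 1
        stable_set = bool(np.array_equal(new_retained, retained))
        if v_prev is not None:
            change = np.max(np.abs(v - v_prev) / v_prev)
            if change < tol:
                converged = True
        if stable_set:
            # same gene set => same factors next round: fixed point
            converged = True
            retained = new_retained
            v_prev = v
            break
        retained = new_retained
        v_prev = v
        if converged:
            break
    if not converged:
        logger.warning("PoissonSeq did not converge in %d iterations", max_iter)
    return NormalizationResult(
        factors=_standardize(v_prev, Y.columns),
        method="poissonseq",
        retained_genes=frozenset(Y.index[retained]),
        iterations=iterations,
        converged=converged,
    )


def normalize(Y: pd.DataFrame, method: str, **kwargs) -> NormalizationResult:
    """Dispatch to a factor method by name (see :data:`METHODS`)."""
    dispatch = {
        "reference": reference_factors,
        "tc": tc_factors,
        "uq": uq_factors,
        "tmm": tmm_factors,
        "deseq": deseq_factors,
        "deges_tmm": deges_tmm_factors,
        "poissonseq": poissonseq_factors,
    }
    try:
        fn = dispatch[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None
    return fn(Y, **kwargs)
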