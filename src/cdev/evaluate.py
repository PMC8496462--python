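"""Downstream and ground-truth evaluation of a normalization.

Contains the pieces used to judge a normalized matrix: a log-CPM
transform with a small library-size-proportional offset, a moderated
two-sample DE test, ROC/AUC and FPR/FNR against simulated truth, the
fold-change mean-squared-error on reference genes, and a PCA diagnostic
of the reference (spike-in) submatrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError
from .metric import cdev_from_factors
from .normalize import apply_factors

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene differential-expression results at a given FDR."""

    gene_ids: pd.Index
    statistic: pd.Series
    p_value: pd.Series
    q_value: pd.Series
    call: pd.Series
    fdr: float


@dataclass
class EvalReport:
    """Summary metrics of one normalization against ground truth."""

    cdev_to_truth: float
    auc: float
    fpr: float
    fnr: float
    fold_change_mse: float

    def to_dict(self) -> dict:
        return {
            "cdev_to_truth": self.cdev_to_truth,
            "auc": self.auc,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "fold_change_mse": self.fold_change_mse,
        }


def log_cpm(Y: pd.DataFrame, factors=None, prior_mean: float = 1.0) -> pd.DataFrame:
    """log2 counts-per-million of raw counts under a given normalization.

    The normalization enters through the *effective library size*: with
    scaling factors ``v`` (geometric mean ~1, each sample divided by its
    factor), sample j's effective library is ``v_j`` times the geometric
    mean of the raw column sums; without factors it is the raw column sum
    itself (plain total-count scaling).  Each count is increased by a
    per-sample offset proportional to the effective library and averaging
    ``prior_mean`` across samples — deeper samples get a proportionally
    larger pseudo-count — then::

        log2((y_ij + o_j) / (eff_lib_j + 2 * o_j) * 1e6)

    Multiplying the factor vector by any scalar shifts every entry by the
    same constant, leaving all between-sample contrasts unchanged.
    """
    if prior_mean < 0:
        raise ValueError("prior_mean must be >= 0")
    from .normalize import NormalizationResult

    values = Y.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if np.any(lib <= 0):
        raise DegenerateInputError("a sample has zero library size")
    if factors is None:
        eff = lib
    else:
        if isinstance(factors, NormalizationResult):
            factors = factors.factors
        if isinstance(factors, pd.Series):
            v = factors.reindex(Y.columns).to_numpy(dtype=float)
        else:
            v = np.asarray(factors, dtype=float).ravel()
        if v.size != Y.shape[1] or np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise DegenerateInputError("invalid scaling factors for log_cpm")
        eff = np.exp(np.mean(np.log(lib))) * v
    offset = prior_mean * eff / eff.mean()
    cpm = (values + offset) / (eff + 2 * offset) * 1e6
    return pd.DataFrame(np.log2(cpm), index=Y.index, columns=Y.columns)


def _split_two_conditions(columns: pd.Index, conditions) -> tuple[np.ndarray, np.ndarray]:
    cond = pd.Series(conditions)
    if isinstance(cond.index, pd.RangeIndex):
        if len(cond) != len(columns):
            raise DegenerateInputError("condition labels do not match samples")
        cond.index = columns
    else:
        cond.index = cond.index.astype(str)
        if set(cond.index) == set(columns):
            cond = cond.reindex(columns)
        elif len(cond) == len(columns):
            cond.index = columns
        else:
            raise DegenerateInputError("condition labels do not match samples")
    levels = pd.unique(cond)
    if len(levels) != 2:
        raise DegenerateInputError(f"need exactly 2 conditions, got {len(levels)}")
    g1 = np.flatnonzero(cond.to_numpy() == levels[0])
    g2 = np.flatnonzero(cond.to_numpy() == levels[1])
    if g1.size < 2 or g2.size < 2:
        raise DegenerateInputError("each condition needs at least 2 samples")
    return g1, g2


def de_test(
    logX: pd.DataFrame,
    conditions,
    fdr: float = 0.05,
    moderation: str = "shrunk",
    prior_df: float = 4.0,
) -> DEResult:
    """Moderated two-sample t-test per gene on a log-scale matrix.

    ``moderation="pooled"`` is the ordinary equal-variance two-sample t.
    ``"shrunk"`` (default) stabilizes the per-gene pooled variance by
    shrinking it toward a global mean-variance trend (a quadratic fit of
    log-variance on mean log-expression) with ``prior_df`` pseudo-samples
    of weight; the reference distribution gains the prior degrees of
    freedom accordingly.  Multiplicity is controlled by Benjamini-
    Hochberg; ``call`` marks genes with q-value below ``fdr``.
    """
    if moderation not in ("pooled", "shrunk"):
        raise ValueError(f"unknown moderation {moderation!r}")
    g1, g2 = _split_two_conditions(logX.columns, conditions)
    values = logX.to_numpy(dtype=float)
    n1, n2 = g1.size, g2.size
    x1, x2 = values[:, g1], values[:, g2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    if moderation == "shrunk":
        amean = values.mean(axis=1)
        logs2 = np.log2(np.maximum(s2, 1e-10))
        coef = np.polyfit(amean, logs2, deg=2)
        trend = np.maximum(2.0 ** np.polyval(coef, amean), 1e-10)
        s2_post = (prior_df * trend + df_resid * s2) / (prior_df + df_resid)
        df = df_resid + prior_df
    else:
        s2_post = s2
        df = df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m2 - m1) / se, np.where(m2 == m1, 0.0, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    idx = logX.index
    return DEResult(
        gene_ids=idx,
        statistic=pd.Series(t, index=idx, name="t"),
        p_value=pd.Series(p, index=idx, name="p_value"),
        q_value=pd.Series(q, index=idx, name="q_value"),
        call=pd.Series(q < fdr, index=idx, name="call"),
        fdr=fdr,
    )


def roc_auc(statistic, truth) -> float:
    """Rank-based AUC of |statistic| for discriminating true DE genes."""
    truth = np.asarray(truth, dtype=bool)
    score = np.abs(np.asarray(statistic, dtype=float))
    if truth.all() or not truth.any():
        raise DegenerateInputError("truth must contain both classes")
    # infinities break rank computation in some backends; cap them
    finite_max = score[np.isfinite(score)].max(initial=0.0)
    score = np.where(np.isfinite(score), score, finite_max + 1.0)
    return float(roc_auc_score(truth, score))


def fpr_fnr(calls, truth) -> tuple[float, float]:
    """False positive and false negative rates of DE calls vs truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise DegenerateInputError("truth must contain both classes")
    fp = np.sum(calls & ~truth)
    tn = np.sum(~calls & ~truth)
    fn = np.sum(~calls & truth)
    tp = np.sum(calls & truth)
    return float(fp / (fp + tn)), float(fn / (fn + tp))


def fold_change_mse(
    X: pd.DataFrame,
    conditions,
    references,
    log_base: float = 2.0,
) -> float:
    """Mean squared log fold-change of reference genes between conditions.

    Reference genes are non-differential by definition, so their expected
    between-condition fold-change is one and any departure is
    normalization error.  Genes whose mean vanishes in either condition
    are dropped (with a log message) rather than erroring — real
    spike-in sets contain dropouts.
    """
    g1, g2 = _split_two_conditions(X.columns, conditions)
    refs = pd.Index(list(references)).astype(str)
    if refs.empty:
        raise DegenerateInputError("empty reference set")
    sub = X.loc[refs.intersection(X.index)].to_numpy(dtype=float)
    if sub.shape[0] == 0:
        raise DegenerateInputError("no reference genes present in the matrix")
    m1 = sub[:, g1].mean(axis=1)
    m2 = sub[:, g2].mean(axis=1)
    usable = (m1 > 0) & (m2 > 0)
    dropped = int((~usable).sum())
    if dropped:
        logger.info("fold_change_mse: dropped %d reference genes with a zero "
                    "condition mean", dropped)
    if not usable.any():
        raise DegenerateInputError("no usable reference gene (zero condition means)")
    lfc = np.log(m2[usable] / m1[usable]) / np.log(log_base)
    return float(np.mean(lfc**2))


def spikein_pca(
    X: pd.DataFrame,
    references,
    conditions=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the first two PCs of the reference submatrix.

    The reference rows are log2(x+1)-transformed, gene-centered, and
    decomposed by SVD with samples as observations.  After a correct
    normalization the references carry no structured variation, so no
    component should separate sample groups; reference rows still scaled
    by a condition-confounded factor instead show the conditions split
    along PC1.  Component signs are fixed by making each component's
    largest-magnitude gene loading positive.  Returns the per-sample
    scores and the variance fractions of the two components.
    """
    refs = pd.Index(list(references)).astype(str)
    sub = X.loc[refs.intersection(X.index)]
    if sub.shape[0] < 3 or sub.shape[1] < 3:
        raise DegenerateInputError("need >= 3 reference genes and >= 3 samples")
    logged = np.log2(sub.to_numpy(dtype=float) + 1.0)
    centered = (logged - logged.mean(axis=1, keepdims=True)).T  # samples x genes
    if np.allclose(centered, 0):
        raise DegenerateInputError("reference submatrix is constant across samples")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(min(2, s.size)):
        lead = np.argmax(np.abs(Vt[k]))
        if Vt[k, lead] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :2] * s[:2]
    total = np.sum(s**2)
    var_frac = (s[:2] ** 2) / total
    frame = pd.DataFrame(scores, index=X.columns, columns=["PC1", "PC2"])
    if conditions is not None:
        frame["condition"] = pd.Series(conditions).to_numpy()
    return frame, var_frac


def evaluate_normalization(
    Y: pd.DataFrame,
    factors,
    truth_factors,
    conditions,
    references,
    de_mask,
    fdr: float = 0.05,
) -> EvalReport:
    """Full report for one normalization of a count matrix.

    ``factors`` and ``truth_factors`` are the candidate and ground-truth
    scaling vectors of the same raw counts ``Y``; the deviation between
    them is computed exactly from the factors.  DE calling runs on the
    candidate-normalized log-CPM.
    """
    from .normalize import NormalizationResult

    if isinstance(factors, NormalizationResult):
        factors = factors.factors
    if isinstance(truth_factors, NormalizationResult):
        truth_factors = truth_factors.factors
    dev = cdev_from_factors(truth_factors, factors).value
    X = apply_factors(Y, factors)
    de = de_test(log_cpm(Y, factors), conditions, fdr=fdr)
    mask = np.asarray(de_mask, dtype=bool)
    auc = roc_auc(de.statistic, mask)
    fpr, fnr = fpr_fnr(de.call, mask)
    mse = fold_change_mse(X, conditions, references)
    return EvalReport(
        cdev_to_truth=float(dev), auc=auc, fpr=fpr, fnr=fnr, fold_change_mse=mse
    )
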