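"""Negative-binomial simulator for two-condition RNA-seq count matrices.

The generative model: a heavy-tailed baseline relative abundance is drawn
for ``n`` genes (log-normal on the expression scale, renormalized to a
composition); a chosen fraction of genes is flagged differential and
assigned multiplicative fold-changes — either one common value applied to
every differential gene (homogeneous) or per-gene values drawn uniformly,
half up-regulated with factor ``Unif(1, 10)`` and half down-regulated
with factor ``1/Unif(1, 10)`` (heterogeneous).  Condition-2 proportions
are the fold-changed baseline renormalized to sum to one, so samples stay
compositions: adding reads to differential genes necessarily dilutes the
read share of every stable gene, which is exactly why the read fraction
of unchanged reference genes (e.g. spike-ins) fluctuates across samples.
Counts are drawn per sample from a negative binomial with mean
``mu_ij = L_j * p_ij`` and variance ``mu + phi * mu^2``, with the library
size ``L_j`` jittered uniformly around its mean.

The true reference set — the input to ground-truth scaling — is the set
of all non-differential genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_baseline",
    "assign_fold_changes",
    "sample_counts",
    "simulate",
]


@dataclass
class SimConfig:
    """Configuration of one simulated two-condition experiment.

    Parameters
    ----------
    n_genes:
        Number of genes.
    n_samples:
        Samples per condition, ``(m1, m2)``.
    de_fraction:
        Fraction of genes that are differential, in [0, 1).
    mode:
        ``"homogeneous"`` (single fold-change ``fold_change`` for all
        differential genes) or ``"heterogeneous"`` (per-gene uniform
        fold-changes, half up / half down).
    fold_change:
        The common fold-change in homogeneous mode (> 1); ignored in
        heterogeneous mode.
    fc_range:
        Range of the uniform fold-change magnitude in heterogeneous mode.
    dispersion:
        NB dispersion phi (Var = mu + phi mu^2).  0.1 is typical of bulk
        RNA-seq biological replicates.  Values below 1e-8 fall back to
        Poisson sampling.
    dispersion_trend:
        Optional ``(phi0, phi1)`` for a mean-dependent dispersion
        ``phi(mu) = phi0 + phi1 / mu``; overrides ``dispersion``.
    mean_library_size:
        Expected total reads per sample.
    library_size_jitter:
        Half-width of the uniform relative jitter on library sizes.
    baseline_meanlog, baseline_sdlog:
        Log-normal parameters of the baseline abundance distribution.
    seed:
        Master seed; identical configs reproduce bit-identical output.
    """

    n_genes: int = 10000
    n_samples: tuple[int, int] = (20, 20)
    de_fraction: float = 0.5
    mode: str = "heterogeneous"
    fold_change: float = 4.0
    fc_range: tuple[float, float] = (1.0, 10.0)
    dispersion: float = 0.1
    dispersion_trend: tuple[float, float] | None = None
    mean_library_size: float = 1e6
    library_size_jitter: float = 0.2
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        m1, m2 = self.n_samples
        if m1 < 1 or m2 < 1:
            raise ValueError("each condition needs at least one sample")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "homogeneous" and self.de_fraction > 0 and self.fold_change <= 1:
            raise ValueError("homogeneous mode requires fold_change > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be > 0")
        if not 0 <= self.library_size_jitter < 1:
            raise ValueError("library_size_jitter must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """A simulated count matrix together with its generative ground truth."""

    counts: pd.DataFrame
    baseline_proportions: np.ndarray
    de_mask: np.ndarray
    fold_changes: np.ndarray
    condition_labels: pd.Series
    reference_set: frozenset
    library_sizes: np.ndarray
    config: SimConfig = field(repr=False, default=None)

    @property
    def de_gene_ids(self) -> pd.Index:
        return self.counts.index[self.de_mask]


def generate_baseline(
    n_genes: int,
    seed: int,
    meanlog: float = 0.0,
    sdlog: float = 2.0,
) -> np.ndarray:
    """Draw baseline relative abundances for ``n_genes`` genes.

    Log-normal expression levels renormalized to a composition; the
    default sdlog of 2 yields the strong right tail characteristic of
    transcript abundance (a few genes absorb most reads).
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    levels = rng.lognormal(mean=meanlog, sigma=sdlog, size=n_genes)
    return levels / levels.sum()


def assign_fold_changes(
    n_genes: int,
    de_fraction: float,
    mode: str = "heterogeneous",
    fold_change: float = 4.0,
    fc_range: tuple[float, float] = (1.0, 10.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag differential genes and assign their fold-changes.

    Returns ``(de_mask, fold_changes)``; non-differential genes have
    fold-change 1.  In heterogeneous mode exactly half of the
    differential genes (ceil/floor split when odd) are up-regulated with
    multiplicative factor ``Unif(lo, hi)`` and the rest down-regulated
    with factor ``1/Unif(lo, hi)`` — the multiplicative reading of the
    signed-uniform fold-change convention, since a negative multiplier is
    meaningless for counts.
    """
    if not 0 <= de_fraction < 1:
        raise ValueError("de_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_de = int(round(de_fraction * n_genes))
    de_mask = np.zeros(n_genes, dtype=bool)
    fold_changes = np.ones(n_genes)
    if n_de == 0:
        return de_mask, fold_changes
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_mask[de_idx] = True
    if mode == "homogeneous":
        if fold_change <= 1:
            raise ValueError("homogeneous mode requires fold_change > 1")
        fold_changes[de_idx] = fold_change
    elif mode == "heterogeneous":
        lo, hi = fc_range
        n_up = (n_de + 1) // 2
        up_idx = de_idx[:n_up]
        down_idx = de_idx[n_up:]
        fold_changes[up_idx] = rng.uniform(lo, hi, size=n_up)
        fold_changes[down_idx] = 1.0 / rng.uniform(lo, hi, size=n_de - n_up)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return de_mask, fold_changes


def sample_counts(
    proportions: np.ndarray,
    fold_changes: np.ndarray,
    config: SimConfig,
    de_mask: np.ndarray | None = None,
) -> SimTruth:
    """Draw the count matrix given baseline proportions and fold-changes.

    Condition-2 expected proportions are ``baseline * fold_change``
    renormalized to sum to one.  Counts are NB with mean ``L_j * p_ij``
    and variance ``mu + phi mu^2``; dispersion below 1e-8 switches to the
    Poisson limit.
    """
    proportions = np.asarray(proportions, dtype=float)
    fold_changes = np.asarray(fold_changes, dtype=float)
    n = proportions.size
    if fold_changes.size != n:
        raise ValueError("proportions and fold_changes length mismatch")
    if de_mask is None:
        de_mask = fold_changes != 1.0
    m1, m2 = config.n_samples
    m = m1 + m2
    # independent substreams so changing one stage never perturbs another;
    # children 0 and 1 are reserved for the baseline and fold-change draws
    _, _, ss_lib, ss_counts = np.random.SeedSequence(config.seed).spawn(4)
    rng_lib = np.random.default_rng(ss_lib)
    rng_counts = np.random.default_rng(ss_counts)

    jit = config.library_size_jitter
    lib = config.mean_library_size * (1.0 + rng_lib.uniform(-jit, jit, size=m))

    p1 = proportions / proportions.sum()
    shifted = proportions * fold_changes
    p2 = shifted / shifted.sum()
    P = np.empty((n, m))
    P[:, :m1] = p1[:, None]
    P[:, m1:] = p2[:, None]
    mu = P * lib[None, :]

    if config.dispersion_trend is not None:
        phi0, phi1 = config.dispersion_trend
        phi = phi0 + phi1 / np.maximum(mu, 1e-8)
    else:
        phi = np.full_like(mu, config.dispersion)

    counts = np.empty((n, m), dtype=np.int64)
    poisson_like = phi < 1e-8
    if poisson_like.any():
        counts[poisson_like] = rng_counts.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        r = 1.0 / phi[nb]
        p_nb = r / (r + mu[nb])
        counts[nb] = rng_counts.negative_binomial(r, p_nb)

    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")
    sample_ids = pd.Index(
        [f"c1_s{j + 1:02d}" for j in range(m1)]
        + [f"c2_s{j + 1:02d}" for j in range(m2)]
    )
    labels = pd.Series([1] * m1 + [2] * m2, index=sample_ids, name="condition")
    return SimTruth(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        baseline_proportions=p1,
        de_mask=de_mask,
        fold_changes=fold_changes,
        condition_labels=labels,
        reference_set=frozenset(gene_ids[~de_mask]),
        library_sizes=lib,
        config=config,
    )


def simulate(config: SimConfig) -> SimTruth:
    """Run the full pipeline: baseline, fold-changes, counts."""
    base_seed, fc_seed, _, _ = np.random.SeedSequence(config.seed).spawn(4)
    proportions = generate_baseline(
        config.n_genes,
        seed=base_seed,
        meanlog=config.baseline_meanlog,
        sdlog=config.baseline_sdlog,
    )
    de_mask, fold_changes = assign_fold_changes(
        config.n_genes,
        config.de_fraction,
        mode=config.mode,
        fold_change=config.fold_change,
        fc_range=config.fc_range,
        seed=fc_seed,
    )
    return sample_counts(proportions, fold_changes, config, de_mask=de_mask)
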