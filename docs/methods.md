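# Methods

## The deviation metric

Given gene-by-sample matrices **X** (candidate normalization) and **A**
(ground truth) of identical shape and ordering, the transformation
**B** with **XB** = **A** is scored by its 2-norm condition number
κ(**B**) = σ_max/σ_min, computed as cdev(**X**, **A**) = κ(**X**⁺**A**).
A valid normalization is unique only up to an overall scalar, and **B** =
α**I** gives κ = 1; any disagreement between per-sample scalings inflates
κ. The SVD of **X**⁺**A** always exists, so the metric is defined for any
same-shape pair, and it is symmetric exactly when **B** is diagonal, i.e.
when the two matrices differ by a column scaling only. Outside the
global-scaling setting the number is still computable but loses its
interpretation, so the package deliberately supports nothing beyond
same-shape, same-ordering comparisons (no gene-set intersection, no
batch-correction style transformations).

Numerical choices:

* **Rank tolerance.** Singular values of **X** below `sigma_tol` ×
  σ_max(**X**) (default 1e-12) are dropped from the pseudoinverse. If
  σ_min(**X**⁺**A**)/σ_max(**X**⁺**A**) falls below the same tolerance
  the result is reported as `inf` rather than as an unstable large
  number: a rank-deficient **X** makes the transformation rank-deficient
  and the deviation genuinely unbounded. The tolerance is our choice; no
  canonical value exists for this quantity.
* **Fast path.** When **A** is a column scaling of **X**, the diagonal of
  **B** equals **A**[i,:]/**X**[i,:] for any gene row i positive in both
  matrices. Rather than an arbitrary row — fragile for low-count rows —
  the default pivot is the eligible row whose smallest entry is largest
  (`maximin`), and a second eligible row must reproduce the ratios within
  1e-6 relative; disagreement or the absence of an eligible row triggers
  a logged fallback to the SVD route. Round-tripping matrices through
  text at limited precision is the typical way to trip this cross-check.
* **Factor shortcut.** When both matrices are scalings of one raw count
  matrix (the dominant benchmarking case), cdev is computed exactly in
  O(m) as max(u/v)/min(u/v) from the two factor vectors.
* **Linear scale only.** Negative entries (the signature of
  log-transformed input) are rejected; the metric is defined on
  count-like matrices.
* **All-zero samples** in **X** make the problem degenerate and raise an
  error rather than returning a number.

## Ground-truth scaling and reference selection

With a reference set *R* of genes stable across samples, sample *j*'s
factor is ν_j = Σ_{i∈R} y_ij / (Π_k Σ_{i∈R} y_ik)^{1/m}. The factor
vector has geometric mean exactly 1 and scaling by it equalizes the
reference sums across samples exactly. All factor methods in the package
are standardized to geometric mean 1; the magnitude of a factor vector
is irrelevant to validity (and, as the tests verify, to DE outcomes),
standardization only keeps normalized values on a count-like scale.

For spike-in data, candidates are rows whose ID starts with `ERCC-`
(exact, case-sensitive; a regex escape hatch covers other schemes), and a
candidate is a usable reference only if it has at least *t* reads in
every sample (default *t* = 10, the low end of the usual 10–100 range).
The selection is monotone in *t*, and the error path reports the largest
*t* that would retain at least one candidate, to make the
retention/threshold trade-off explicit. The packaged control list
contains the 92 canonical ERCC identifiers.

A note on read fractions: the proportion of reads mapping to spike-ins
*must* vary across samples whenever the biological composition varies
(two genes at levels 1/1 versus 1/3 put the stable gene at 50% versus
25% of reads). This fluctuation is an expected property of raw counts,
not evidence against spike-ins as references.

## Normalizers

The six compared methods follow their standard simplified formulations —
deliberately not the exact published implementations (edgeR's weighted
log-scale TMM, the PoissonSeq package's estimator), whose extra
machinery is out of scope here:

* **TC** — factors ∝ per-sample total counts.
* **UQ** — factors ∝ the 75th percentile over genes detected in at least
  one sample; percentile by linear interpolation between order statistics
  (numpy's default, the "type 7" convention), fixed so results are
  reproducible.
* **TMM** — per sample, genes positive in both it and the reference
  sample (default: the first; configurable, since an unusually shallow
  first sample is a real hazard) are trimmed two-sided by log-ratio
  (30%) and abundance (5%); the factor is the plain mean of count ratios
  over survivors. Requires ≥ 20 shared-positive genes per sample.
* **DESeq** — median over all-positive genes of the ratio to the
  per-gene geometric-mean pseudo-reference.
* **DEGES/TMM** — TMM, then eliminate genes the internal DE caller flags
  at BH FDR < 0.10 (the conventional elimination default), then TMM on
  the remainder; one iteration by default, more supported with a
  convergence flag at 1e-8 max-relative factor change.
* **PoissonSeq** — iterate: factors are the retained genes' count shares
  per sample; expected counts under the no-DE Poisson null are
  v_j × (gene total); each gene's chi-squared goodness-of-fit is
  computed and the central inter-quartile band is retained. Stops on a
  stable retained set or factor change < 1e-8; hitting the iteration cap
  flags non-convergence (common on pure-noise data where band membership
  jitters harmlessly). The central-band rule is one reasonable reading of
  "remove genes ranking poorly for goodness of fit"; the original
  package's exact retained-set rule differs.

Zero handling is method-specific as described: UQ drops all-zero rows,
TMM uses shared-positive genes, DESeq drops genes with any zero,
reference scaling tolerates zeros inside *R* as long as each sample's
reference sum is positive.

### A known failure mode of elimination strategies

DEGES improves on TMM when the DE caller can still see the truth through
the biased first-pass normalization. With one-sided fold-changes at
moderate DE fractions (≤ ~40%) this holds and the elimination reliably
tightens the factors. At 50% one-sided DE the trimmed mean can no longer
exclude the DE mode, the apparent log-fold-changes of *both* gene groups
sit far from zero, the caller flags nearly everything, and the surviving
"non-DE" genes are the uninformative boundary between the two modes —
re-normalizing on them does not help and can hurt. The test suite pins
the improvement at 30% DE where the mechanism genuinely operates.

## The simulator

Two-condition negative-binomial counts with full generative truth:

* **Baseline abundance**: log-normal (meanlog 0, sdlog 2) renormalized to
  a composition — a parametric stand-in for empirical abundance
  distributions, giving the characteristic heavy right tail (a Gini
  coefficient well above 0.5: a few genes absorb most reads).
  Absolute deviation magnitudes depend on this choice; all monotone and
  correlational behaviors do not.
* **Differential genes**: a fraction *k* of genes, fold-changes either a
  single value f > 1 (homogeneous) or per-gene Unif(1, 10) up and
  1/Unif(1, 10) down in equal halves (heterogeneous) — the multiplicative
  reading of the signed-uniform convention, since a negative multiplier
  is meaningless for counts. Log-fold-changes are symmetric about zero in
  the heterogeneous mode.
* **Condition-2 proportions** are the fold-changed baseline renormalized
  to sum to one: samples are compositions, so up-regulation necessarily
  dilutes every stable gene's read share. This single mechanism produces
  the condition-level scaling error that contaminated reference sets and
  global normalizers inherit.
* **Counts**: y_ij ~ NB(μ = L_j p_ij, Var = μ + φμ²) with dispersion
  φ = 0.1 (typical bulk biological replicates; an optional trend
  φ(μ) = φ0 + φ1/μ is available), library sizes 1e6 ± 20% uniform
  jitter. φ below 1e-8 switches to Poisson sampling.
* **Determinism**: one master seed; baseline, fold-change, library-size
  and count draws use disjoint substreams, so identical configs are
  bit-reproducible and changing one stage leaves the others untouched.

What the simulator does *not* model: read-level effects, gene length and
GC bias, batch effects, outlier samples, and correlation between genes.
Passing benchmarks here therefore demonstrate the metric's behavior under
clean global-scaling violations, not robustness to every real-data
pathology; the real-data analogues (spike-in selection, the PCA
diagnostic) are exercised on synthetic stand-ins.

## Evaluation

* **log-CPM**: log2((y_ij + o_j)/(eff_j + 2 o_j) × 1e6) on raw counts,
  where the effective library eff_j is the factor ν_j times the geometric
  mean of raw column sums (or the raw column sum when no factors are
  given) and the offset o_j ∝ eff_j averages `prior_mean` (default 1)
  across samples. Carrying the normalization through effective library
  sizes — rather than re-deriving library sizes from the scaled matrix,
  which would cancel the factors — is what makes DE results respond to
  normalization quality while remaining exactly invariant to the factor
  vector's overall magnitude.
* **DE caller**: per-gene two-sample t on log-CPM; the default
  "shrunk" moderation pulls each gene's pooled variance toward a global
  quadratic mean-variance trend with 4 pseudo-samples of prior weight and
  adds the prior degrees of freedom to the reference distribution. BH
  q-values; calls at FDR < 0.05 by default (the calling threshold behind
  published FPR curves is not standardized, so absolute FPR values are
  not treated as comparable across implementations).
* **AUC** uses the full |statistic| ranking (Mann–Whitney with tie
  handling via scikit-learn); FPR/FNR use the binary calls. FNR is
  reported but is a weak indicator: calling everything differential
  achieves zero FNR, and bad normalization inflates false positives far
  more than misses.
* **Fold-change MSE** is the mean squared log2 ratio of condition means
  over reference genes (expected fold-change 1). References with a zero
  mean in either condition are dropped with a log message — real
  spike-in sets contain dropouts. The metric is blind to mis-scalings
  that repeat identically in both conditions (factors (1, 2) in each
  condition give MSE 0 at cdev 2); the shipped fixture pins this
  ambiguity, which cdev resolves.
* **Reference PCA diagnostic**: log2(x+1) of the reference rows,
  gene-centered, SVD with samples as observations; signs fixed by making
  each component's largest-magnitude loading positive. Condition-
  confounded scaling shows up as condition separation on PC1; after
  correct scaling the references carry no structured variation.

## Experiments and problem sizes

All experiments are pure functions of a config (one master seed,
deterministic substreams per replicate/draw; tables are bit-reproducible
and written as append-safe TSV with a JSON sidecar recording the resolved
config and package version).

* **Contamination sweep**: scaling sets of 2000 genes mixing true
  references with a fraction c ∈ {0, 0.1, …, 0.9} of differential genes;
  the set size is chosen so that subset-sampling noise at c = 0 (cdev
  ≈ 1.1) stays well below the contamination signal. Sweeps use 10000
  genes, 20+20 samples, 50% DE, heterogeneous fold-changes, 5 replicates.
* **Normalizer comparison**: DE fractions 0.1–0.9, same simulator
  settings, 5 replicates; per-method failures become flagged rows, not
  run failures.
* **cdev–MSE concordance**: 4000 genes, 15+15 samples, 100 random-set
  normalizations per DE fraction with random contamination levels to span
  a wide quality range.
* **Random-reference null**: subsets of the true references versus
  random same-size gene sets (up to 100 redraws when a random set has a
  zero sample sum); subset scalings sit well below random ones, and the
  random-set deviation grows with the simulated between-condition
  fold-change.

Desk-scale defaults (10000 genes × 40 samples, 5 replicates) keep the
full default experiment battery and test suite under a minute of compute;
`configs/normalizer_comparison_full.yaml` ships the 50000-gene setting
for users who want the large version.

## Known limitations

* The simplified TMM and PoissonSeq forms rank normalizers the same way
  as the originals in our experiments but produce different absolute
  factors; do not compare factor values against edgeR/PoissonSeq output.
* At extreme DE fractions (≥ 0.9) the PoissonSeq-style filter sometimes
  finds a self-consistent gene subset and lands closer to truth
  (cdev ≈ 1.4–1.8) than the other methods; the qualitative claim that no
  global normalizer stabilizes the references there holds for its typical
  runs but not for every replicate.
* cdev compares two normalizations of the *same* experiment; it says
  nothing about transformations that are not global scalings, and the
  advisory quality bands (≈ 2 for near-homogeneous designs, ≈ 5–10 for
  heterogeneous ones) are dataset-dependent guidelines, not enforced
  thresholds.
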