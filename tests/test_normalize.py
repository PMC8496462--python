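"""Scaling-factor methods: hand-checked values, oracles, and properties."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from cdev import (
    SimConfig,
    apply_factors,
    cdev_from_factors,
    deges_tmm_factors,
    deseq_factors,
    normalize,
    poissonseq_factors,
    reference_factors,
    simulate,
    tc_factors,
    tmm_factors,
    uq_factors,
)
from cdev.exceptions import (
    DegenerateInputError,
    DegenerateReferenceError,
    InsufficientGenesError,
)


def frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestReferenceFactors:
    def test_hand_example(self):
        Y = frame([[10, 20], [30, 60]], genes=["gene1", "gene2"])
        res = reference_factors(Y, ["gene1"])
        expected = [10 / np.sqrt(200), 20 / np.sqrt(200)]
        assert res.factors.to_numpy() == pytest.approx(expected, rel=1e-12)
        A = apply_factors(Y, res.factors)
        # after scaling the reference level is sqrt(200) in both samples
        assert A.loc["gene1"].to_numpy() == pytest.approx(
            [np.sqrt(200)] * 2, rel=1e-12
        )

    def test_identical_columns_give_unit_factors(self):
        Y = frame(np.tile([[5], [9], [2]], (1, 4)))
        res = reference_factors(Y, ["g0", "g2"])
        assert res.factors.to_numpy() == pytest.approx(np.ones(4))

    def test_factor_product_is_one(self, rng):
        Y = frame(rng.integers(1, 1000, (30, 7)))
        res = reference_factors(Y, [f"g{i}" for i in range(0, 30, 3)])
        assert np.prod(res.factors.to_numpy()) == pytest.approx(1.0, abs=1e-9)

    def test_equalizes_reference_sums(self, rng):
        Y = frame(rng.integers(0, 500, (50, 6)))
        refs = [f"g{i}" for i in range(10)]
        res = reference_factors(Y, refs)
        A = apply_factors(Y, res.factors)
        sums = A.loc[refs].sum(axis=0).to_numpy()
        assert np.max(np.abs(sums - sums[0]) / sums[0]) <= 1e-12

    def test_zero_reference_sum_errors(self):
        Y = frame([[0, 5], [3, 4]])
        with pytest.raises(DegenerateReferenceError):
            reference_factors(Y, ["g0"])

    def test_missing_reference_errors(self):
        Y = frame([[1, 2], [3, 4]])
        with pytest.raises(DegenerateReferenceError):
            reference_factors(Y, ["nope"])


class TestApplyFactors:
    def test_identity_and_hand_case(self):
        Y = frame([[2, 4]])
        assert apply_factors(Y, [1, 1]).equals(Y)
        assert apply_factors(Y, [2, 4]).to_numpy()[0] == pytest.approx([1, 1])

    def test_round_trip(self, rng):
        Y = frame(rng.integers(0, 100, (20, 5)))
        v = rng.uniform(0.5, 2.0, 5)
        back = apply_factors(apply_factors(Y, v), 1.0 / v)
        assert np.max(np.abs(back.to_numpy() - Y.to_numpy())) <= 1e-12

    def test_non_positive_factor_rejected(self):
        with pytest.raises(DegenerateInputError):
            apply_factors(frame([[1, 2]]), [1, 0])


class TestTotalCount:
    def test_hand_example(self):
        Y = frame([[40, 100], [60, 200]])  # column sums 100 and 300
        expected = [100 / np.sqrt(30000), 300 / np.sqrt(30000)]
        assert tc_factors(Y).factors.to_numpy() == pytest.approx(expected)

    def test_gene_order_invariance(self, rng):
        Y = frame(rng.integers(1, 100, (25, 4)))
        shuffled = Y.sample(frac=1, random_state=1)
        assert tc_factors(Y).factors.to_numpy() == pytest.approx(
            tc_factors(shuffled).factors.to_numpy()
        )


class TestUpperQuartile:
    def test_all_zero_rows_excluded(self, rng):
        Y = frame(rng.integers(1, 100, (30, 4)))
        padded = pd.concat([Y, frame(np.zeros((5, 4)), genes=[f"z{i}" for i in range(5)])])
        assert uq_factors(padded).factors.to_numpy() == pytest.approx(
            uq_factors(Y).factors.to_numpy()
        )
        assert not any(g.startswith("z") for g in uq_factors(padded).retained_genes)

    def test_percentile_convention(self):
        # one column (1, 2, 3, 100): type-7 upper quartile = 27.25
        Y = frame(np.column_stack([[1, 2, 3, 100], [1, 2, 3, 100]]))
        res = uq_factors(Y)
        assert res.factors.to_numpy() == pytest.approx([1.0, 1.0])
        # the underlying quartile drives the ratio against a uniform column
        Y2 = frame(np.column_stack([[1, 2, 3, 100], [27.25, 27.25, 27.25, 27.25]]))
        ratio = uq_factors(Y2).factors
        assert ratio.iloc[0] == pytest.approx(ratio.iloc[1])

    def test_identical_columns(self):
        Y = frame(np.tile([[3], [8], [1], [40]], (1, 5)))
        assert uq_factors(Y).factors.to_numpy() == pytest.approx(np.ones(5))


class TestDESeq:
    def test_hand_example(self):
        Y = frame([[2, 4], [3, 6], [5, 10]])
        expected = [1 / np.sqrt(2), np.sqrt(2)]
        assert deseq_factors(Y).factors.to_numpy() == pytest.approx(expected)

    def test_zero_gene_ignored(self):
        Y = frame([[2, 4], [3, 6], [5, 10]])
        padded = pd.concat([Y, frame([[0, 7]], genes=["zz"])])
        assert deseq_factors(padded).factors.to_numpy() == pytest.approx(
            deseq_factors(Y).factors.to_numpy()
        )
        assert "zz" not in deseq_factors(padded).retained_genes

    def test_identical_columns(self, rng):
        Y = frame(np.tile(rng.integers(1, 50, (10, 1)), (1, 3)))
        assert deseq_factors(Y).factors.to_numpy() == pytest.approx(np.ones(3))


class TestTMM:
    def test_pure_column_scaling_recovers_factors(self, rng):
        # noiseless non-DE profile scaled per sample: every gene ratio to
        # the reference sample equals the sample's scalar
        base = rng.integers(20, 1000, (100, 1)).astype(float)
        d = np.array([1.0, 2.0, 0.5, 1.5])
        Y = frame(base * d)
        res = tmm_factors(Y)
        assert res.factors.to_numpy() == pytest.approx(d / gmean(d), rel=1e-12)

    def test_identical_columns_give_unit_factors(self, rng):
        Y = frame(np.tile(rng.integers(1, 500, (60, 1)), (1, 5)))
        assert tmm_factors(Y).factors.to_numpy() == pytest.approx(np.ones(5))

    def test_brute_force_oracle(self):
        truth = simulate(SimConfig(n_genes=500, n_samples=(2, 2),
                                   de_fraction=0.3, seed=11))
        Y = truth.counts
        vals = Y.to_numpy(dtype=float)
        m = vals.shape[1]
        trim_m, trim_a = 0.30, 0.05
        raw = np.ones(m)
        for j in range(1, m):
            shared = (vals[:, j] > 0) & (vals[:, 0] > 0)
            yj, yr = vals[shared, j], vals[shared, 0]
            M = np.log2(yj / yr)
            A = 0.5 * np.log2(yj * yr)
            n = yj.size
            km, ka = int(np.floor(trim_m * n)), int(np.floor(trim_a * n))
            keep_m = set(np.argsort(M, kind="stable")[km : n - km])
            keep_a = set(np.argsort(A, kind="stable")[ka : n - ka])
            keep = sorted(keep_m & keep_a)
            raw[j] = np.mean(yj[keep] / yr[keep])
        assert tmm_factors(Y).factors.to_numpy() == pytest.approx(
            raw / gmean(raw), rel=1e-12
        )


class TestDEGES:
    def test_zero_iterations_equal_tmm(self, het_sim):
        Y = het_sim.counts
        res = deges_tmm_factors(Y, het_sim.condition_labels, n_iter=0)
        assert res.factors.to_numpy() == pytest.approx(
            tmm_factors(Y).factors.to_numpy()
        )

    def test_null_data_keeps_most_genes(self):
        truth = simulate(SimConfig(n_genes=2000, n_samples=(6, 6),
                                   de_fraction=0.0, library_size_jitter=0.0,
                                   seed=21))
        res = deges_tmm_factors(truth.counts, truth.condition_labels, fdr=0.10)
        assert len(res.retained_genes) >= 0.85 * 2000
        assert np.max(np.abs(res.factors.to_numpy() - 1.0)) < 0.1

    def test_improves_on_tmm_under_asymmetric_de(self):
        # one-sided fold-changes bias TMM; eliminating called genes and
        # re-normalizing recovers factors closer to the ground truth
        wins = 0
        for seed in range(10):
            truth = simulate(SimConfig(
                n_genes=2000, n_samples=(8, 8), de_fraction=0.3,
                mode="homogeneous", fold_change=4.0, seed=100 + seed,
            ))
            Y = truth.counts
            ref = reference_factors(Y, Y.index[~truth.de_mask]).factors
            plain = cdev_from_factors(ref, tmm_factors(Y).factors).value
            deges = cdev_from_factors(
                ref, deges_tmm_factors(Y, truth.condition_labels).factors
            ).value
            wins += deges < plain
        assert wins >= 8


class TestPoissonSeq:
    def test_poisson_null_factors_near_one(self, rng):
        from cdev import generate_baseline

        p = generate_baseline(5000, seed=31)
        mu = np.outer(p, np.full(10, 2e7))
        Y = frame(rng.poisson(mu))
        res = poissonseq_factors(Y)
        assert np.max(np.abs(res.factors.to_numpy() - 1.0)) < 1e-3

    def test_noiseless_column_scaling(self, rng):
        base = rng.integers(10, 1000, (200, 1)).astype(float)
        s = np.array([1.0, 3.0, 0.5, 2.0])
        Y = frame(base * s)
        res = poissonseq_factors(Y)
        assert res.factors.to_numpy() == pytest.approx(s / gmean(s), rel=1e-9)
        assert res.iterations == 1
        assert res.converged

    def test_procedural_oracle(self):
        truth = simulate(SimConfig(n_genes=10000, n_samples=(20, 20),
                                   de_fraction=0.3, seed=41))
        Y = truth.counts
        vals = Y.to_numpy(dtype=float)
        totals = vals.sum(axis=1)
        usable = totals > 0
        retained = usable.copy()
        v_prev = None
        for _ in range(20):
            colsum = vals[retained].sum(axis=0)
            v = colsum / colsum.sum()
            yhat = np.outer(totals[usable], v)
            gof = np.full(vals.shape[0], np.inf)
            gof[usable] = ((vals[usable] - yhat) ** 2 / yhat).sum(axis=1)
            lo, hi = np.quantile(gof[usable], [0.25, 0.75])
            new = usable & (gof >= lo) & (gof <= hi)
            stop = np.array_equal(new, retained) or (
                v_prev is not None and np.max(np.abs(v - v_prev) / v_prev) < 1e-8
            )
            retained, v_prev = new, v
            if stop:
                break
        res = poissonseq_factors(Y)
        assert res.factors.to_numpy() == pytest.approx(
            v_prev / gmean(v_prev), rel=1e-12
        )

    def test_shrinking_below_minimum_errors(self, rng):
        Y = frame(rng.poisson(100.0, (60, 4)))
        with pytest.raises(InsufficientGenesError):
            poissonseq_factors(Y, min_genes=50, keep_quantiles=(0.45, 0.55))


@pytest.mark.parametrize("method", ["tc", "uq", "tmm", "deseq", "poissonseq"])
def test_geometric_mean_is_one(het_sim, method):
    res = normalize(het_sim.counts, method)
    assert gmean(res.factors.to_numpy()) == pytest.approx(1.0, abs=1e-9)


def test_gene_permutation_invariance(het_sim):
    Y = het_sim.counts
    shuffled = Y.sample(frac=1, random_state=3)
    for method in ("tc", "deseq"):
        assert normalize(Y, method).factors.to_numpy() == pytest.approx(
            normalize(shuffled, method).factors.to_numpy()
        )


def test_subset_consistency_noiseless():
    # constant reference rows + pure column scaling: any reference subset
    # recovers the same normalization as the full set
    rng = np.random.default_rng(5)
    P = np.vstack([np.tile(rng.uniform(10, 100, (6, 1)), (1, 5)),
                   rng.uniform(1, 50, (20, 5))])
    s = rng.uniform(0.5, 2.0, 5)
    Y = frame(P * s)
    refs = [f"g{i}" for i in range(6)]
    full = reference_factors(Y, refs).factors
    for subset in ([refs[0]], refs[:3], refs[2:]):
        sub = reference_factors(Y, subset).factors
        assert cdev_from_factors(full, sub).value == pytest.approx(1.0, abs=1e-12)


def test_subset_beats_random_sets_under_noise(het_sim, het_truth_factors):
    Y = het_sim.counts
    refs = Y.index[~het_sim.de_mask]
    rng = np.random.default_rng(17)
    sub_devs, rand_devs = [], []
    for _ in range(50):
        S = rng.choice(refs.to_numpy(), size=200, replace=False)
        sub_devs.append(
            cdev_from_factors(het_truth_factors,
                              reference_factors(Y, S).factors).value)
        G = rng.choice(Y.index.to_numpy(), size=200, replace=False)
        rand_devs.append(
            cdev_from_factors(het_truth_factors,
                              reference_factors(Y, G).factors).value)
    assert np.median(sub_devs) < np.median(rand_devs)
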