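import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from scprogression._utils import bh_adjust
from scprogression.data_io import CountMatrix
from scprogression.de import (
    PseudobulkMatrix,
    expression_fraction_filter,
    nb_lrt_de,
    pseudobulk_aggregate,
    recurrence_permutation_test,
    wilcoxon_de,
)
from conftest import raw_matrix


def normalized(values):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return CountMatrix(
        sp.csr_matrix(values),
        np.array([f"G{j}" for j in range(n_genes)], dtype=object),
        np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        layer="normalized",
    )


class TestExpressionFractionFilter:
    def test_boundary_single_cell_of_hundred_kept(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[0, 0] = 5  # gene 0 in exactly 1 of 100 cells
        m = raw_matrix(counts)
        mask = expression_fraction_filter(m, min_frac=0.01)
        assert mask[0]  # 1 >= ceil(0.01 * 100) = 1

    def test_undetected_gene_removed(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 0] = 1
        mask = expression_fraction_filter(raw_matrix(counts), min_frac=0.01)
        assert mask.tolist() == [True, False]

    def test_zero_fraction_keeps_everything(self):
        counts = np.zeros((10, 3), dtype=int)
        mask = expression_fraction_filter(raw_matrix(counts), min_frac=0.0)
        assert mask.all()

    def test_empty_subset_rejected(self):
        m = raw_matrix(np.ones((5, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            expression_fraction_filter(m, cells=np.zeros(5, dtype=bool))


class TestWilcoxonDE:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        block = rng.uniform(0.1, 3, size=(10, 5))
        m = normalized(np.vstack([block, block]))
        tab = wilcoxon_de(m, np.arange(10), np.arange(10, 20))
        np.testing.assert_allclose(tab["p"], 1.0)
        np.testing.assert_allclose(tab["log2fc"], 0.0, atol=1e-12)

    def test_asymptotic_matches_independent_rank_computation(self):
        # 100 cells x 50 genes vs scipy's tie/continuity-corrected test
        rng = np.random.default_rng(1)
        X = np.round(rng.gamma(2, 1, size=(100, 50)), 1)  # plenty of ties
        m = normalized(X)
        ia, ib = np.arange(55), np.arange(55, 100)
        tab = wilcoxon_de(m, ia, ib, method="asymptotic")
        for j in range(50):
            ref = mannwhitneyu(
                X[ia, j], X[ib, j], alternative="two-sided",
                method="asymptotic", use_continuity=True,
            ).pvalue
            assert tab["p"].iloc[j] == pytest.approx(ref, abs=1e-10)

    def test_exact_small_groups_match_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(14, 8))  # continuous: no ties
        m = normalized(X - X.min() + 0.1)
        na, nb = 6, 8
        ia, ib = np.arange(na), np.arange(na, na + nb)
        tab = wilcoxon_de(m, ia, ib, method="auto")
        for j in range(8):
            vals = np.concatenate([X[ia, j], X[ib, j]])
            ranks = pd.Series(vals).rank().to_numpy()
            obs_u = ranks[:na].sum() - na * (na + 1) / 2
            us = []
            for combo in itertools.combinations(range(na + nb), na):
                u = ranks[list(combo)].sum() - na * (na + 1) / 2
                us.append(u)
            us = np.array(us)
            p_low = np.mean(us <= obs_u)
            p_high = np.mean(us >= obs_u)
            expected = min(1.0, 2 * min(p_low, p_high))
            assert tab["p"].iloc[j] == pytest.approx(expected, abs=1e-10)

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.5, 4, size=(30, 10))
        a = wilcoxon_de(normalized(X), np.arange(15), np.arange(15, 30))
        b = wilcoxon_de(normalized(np.sqrt(X)), np.arange(15), np.arange(15, 30))
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_log2fc_of_delogged_means(self):
        # group means of expm1(x): 3 and 1 -> log2((3+1)/(1+1)) = 1
        xa = np.full((4, 1), np.log1p(3.0))
        xb = np.full((4, 1), np.log1p(1.0))
        m = normalized(np.vstack([xa, xb]))
        tab = wilcoxon_de(m, np.arange(4), np.arange(4, 8))
        assert tab["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_pct_fields_and_deg_flag(self):
        X = np.zeros((8, 1))
        X[:4, 0] = [2.0, 2.0, 0.0, 0.0]
        m = normalized(X)
        tab = wilcoxon_de(m, np.arange(4), np.arange(4, 8))
        assert tab["pct_a"].iloc[0] == pytest.approx(0.5)
        assert tab["pct_b"].iloc[0] == 0.0

    def test_empty_group_rejected(self):
        m = normalized(np.ones((4, 2)))
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_de(m, np.arange(4), np.array([], dtype=int))


class TestBH:
    def test_textbook_step_up_on_hand_computed_vector(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216])
        # step-up: p_(i) * n / i, cumulative minimum from the largest rank
        raw = p * 10 / np.arange(1, 11)
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(bh_adjust(p), np.minimum(expected, 1),
                                   atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPseudobulk:
    def test_groupwise_sum(self):
        counts = np.array([[2, 3], [0, 1]])
        pb = pseudobulk_aggregate(raw_matrix(counts), ["g1", "g1"])
        np.testing.assert_array_equal(pb.counts.loc["g1"], [2, 4])
        assert pb.meta.loc["g1", "n_cells"] == 2

    def test_singleton_groups_reproduce_cells(self):
        counts = np.array([[2, 3], [5, 7]])
        pb = pseudobulk_aggregate(raw_matrix(counts), ["a", "b"])
        np.testing.assert_array_equal(pb.counts.to_numpy(), counts)

    def test_total_sum_conserved(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2, size=(30, 10))
        groups = rng.choice(["a", "b", "c"], 30)
        pb = pseudobulk_aggregate(raw_matrix(counts), groups)
        assert pb.counts.to_numpy().sum() == counts.sum()

    def test_normalized_layer_rejected(self):
        m = normalized(np.ones((4, 2)))
        with pytest.raises(ValueError, match="raw"):
            pseudobulk_aggregate(m, ["a"] * 4)


class TestNbLrtDE:
    def simulate_pb(self, n_genes=200, fc=1.0, disp=0.1, n_per=4, seed=0,
                    frac_de=0.0):
        # sign-balanced planted effects keep library sizes comparable, so
        # total-count offsets do not absorb the planted fold change
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3, 1, size=n_genes)
        lib = rng.uniform(0.8, 1.2, size=2 * n_per)
        de_genes = rng.random(n_genes) < frac_de
        sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
        effect = np.where(de_genes, fc**sign, 1.0)
        Y = np.zeros((2 * n_per, n_genes), dtype=int)
        for i in range(2 * n_per):
            mu = base * lib[i]
            if i >= n_per:
                mu = mu * effect
            lam = rng.gamma(1 / disp, mu * disp)
            Y[i] = rng.poisson(lam)
        pb = PseudobulkMatrix(
            counts=pd.DataFrame(
                Y, index=[f"s{i}" for i in range(2 * n_per)],
                columns=[f"G{j}" for j in range(n_genes)],
            ),
            meta=pd.DataFrame({"n_cells": [100] * (2 * n_per)}),
        )
        cond = ["a"] * n_per + ["b"] * n_per
        return pb, cond, de_genes, sign

    def test_duplicated_identical_groups_are_null(self):
        # both condition levels get byte-identical pseudobulk rows
        rng = np.random.default_rng(1)
        Y = rng.poisson(50, size=(2, 50))
        pb = PseudobulkMatrix(
            counts=pd.DataFrame(np.vstack([Y, Y]),
                                index=["a1", "a2", "b1", "b2"],
                                columns=[f"G{j}" for j in range(50)]),
            meta=pd.DataFrame({"n_cells": [10] * 4}),
        )
        tab = nb_lrt_de(pb, ["a", "a", "b", "b"])
        assert (tab["p"] > 0.99).all()
        np.testing.assert_allclose(tab["log2fc"], 0.0, atol=1e-6)

    def test_recovers_planted_fold_change(self):
        pb, cond, de_genes, sign = self.simulate_pb(
            n_genes=400, fc=4.0, frac_de=0.2, seed=2
        )
        tab = nb_lrt_de(pb, cond)
        signed = tab["log2fc"].to_numpy() * sign
        med = np.median(signed[de_genes])
        assert med == pytest.approx(2.0, abs=0.15)

    def test_non_integer_counts_rejected(self):
        pb = PseudobulkMatrix(
            counts=pd.DataFrame([[1.5, 2.0], [2.0, 3.0]], index=["a", "b"],
                                columns=["G0", "G1"]),
            meta=pd.DataFrame({"n_cells": [1, 1]}),
        )
        with pytest.raises(ValueError, match="integer"):
            nb_lrt_de(pb, ["a", "b"])

    def test_patient_blocks_raise_power_under_patient_heterogeneity(self):
        # gene-specific patient baselines act as paired noise: conditioning
        # on patient should recover substantially more planted effects while
        # staying roughly calibrated on the unaffected genes
        rng = np.random.default_rng(3)
        n_genes = 300
        base = rng.lognormal(3, 1, size=n_genes)
        de = rng.random(n_genes) < 0.3
        sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
        effect = np.where(de, 2.0**sign, 1.0)
        Y = []
        for _ in range(4):
            pat_eff = rng.lognormal(0, 0.5, size=n_genes)
            for tp in ("i", "a"):
                mu = base * pat_eff * (effect if tp == "a" else 1.0)
                lam = rng.gamma(10, mu / 10)
                Y.append(rng.poisson(lam))
        pb = PseudobulkMatrix(
            counts=pd.DataFrame(np.array(Y),
                                index=[f"s{i}" for i in range(8)],
                                columns=[f"G{j}" for j in range(n_genes)]),
            meta=pd.DataFrame({"n_cells": [10] * 8}),
        )
        cond = ["i", "a"] * 4
        patient = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
        blocked = nb_lrt_de(pb, cond, patient=patient)
        unblocked = nb_lrt_de(pb, cond)
        assert (blocked["p"][de] < 0.05).mean() > (unblocked["p"][de] < 0.05).mean()
        assert (blocked["p"][~de] < 0.05).mean() <= 0.12


class TestRecurrence:
    def test_zero_observed_overlap_has_p_one(self):
        deg = {"p1": {"G1"}, "p2": {"G2"}}
        uni = {"p1": {"G1", "G2", "G3"}, "p2": {"G1", "G2", "G3"}}
        res = recurrence_permutation_test(deg, uni, B=300, seed=0)
        assert res.observed_count_ge_k == 0
        assert res.p > 0.5

    def test_histogram_counts_multiplicities(self):
        deg = {"p1": {"G1", "G2"}, "p2": {"G1"}, "p3": {"G1", "G3"}}
        uni = {p: {f"G{i}" for i in range(1, 8)} for p in deg}
        res = recurrence_permutation_test(deg, uni, B=200, seed=0)
        assert res.histogram[3] == 1  # G1 in all three
        assert res.histogram[1] == 2  # G2, G3
        assert res.observed_count_ge_k == 1

    def test_two_pair_null_matches_hypergeometric_mean(self):
        # overlap of random 5- and 4-subsets of a 20-gene universe
        from scipy.stats import hypergeom

        deg = {"p1": set(), "p2": set()}
        uni = {p: {f"G{i}" for i in range(20)} for p in deg}
        deg["p1"] = {f"G{i}" for i in range(5)}
        deg["p2"] = {f"G{i}" for i in range(4)}
        res = recurrence_permutation_test(deg, uni, B=4000, seed=1)
        expected_mean = hypergeom(20, 5, 4).mean()
        assert res.null_counts.mean() == pytest.approx(expected_mean, rel=0.1)

    def test_planted_recurrence_is_significant(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(2000)]
        forced = genes[:10]
        deg, uni = {}, {}
        for p in range(6):
            extra = list(rng.choice(genes[10:], size=40, replace=False))
            deg[f"p{p}"] = set(forced[:6] + extra) if p < 3 else set(extra)
            uni[f"p{p}"] = set(genes)
        res = recurrence_permutation_test(deg, uni, B=2000, seed=0, k=3)
        assert res.p < 0.001

    def test_statistic_invariant_to_pair_order(self):
        deg = {"p1": {"G1", "G2"}, "p2": {"G1"}}
        uni = {p: {f"G{i}" for i in range(1, 6)} for p in deg}
        a = recurrence_permutation_test(deg, uni, B=200, seed=0)
        b = recurrence_permutation_test(
            dict(reversed(deg.items())), dict(reversed(uni.items())),
            B=200, seed=0,
        )
        assert a.observed_count_ge_k == b.observed_count_ge_k

    def test_reproducible_under_seed(self):
        deg = {"p1": {"G1", "G2"}, "p2": {"G2"}}
        uni = {p: {f"G{i}" for i in range(1, 9)} for p in deg}
        a = recurrence_permutation_test(deg, uni, B=500, seed=3)
        b = recurrence_permutation_test(deg, uni, B=500, seed=3)
        assert a.p == b.p
        np.testing.assert_array_equal(a.null_counts, b.null_counts)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            recurrence_permutation_test({"p1": set()}, {"p1": set()}, B=200)

    def test_degs_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            recurrence_permutation_test(
                {"p1": {"G9"}}, {"p1": {"G1"}}, B=200
            )
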