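import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scprogression.data_io import CountMatrix, GeneSet
from scprogression.signatures import (
    activity_scores,
    metabolic_fraction,
    module_score,
    orient_pseudotime,
    sample_mean_permutation_test,
)
from conftest import raw_matrix


def normalized(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    if gene_ids is None:
        gene_ids = [f"G{j}" for j in range(n_genes)]
    return CountMatrix(
        sp.csr_matrix(values),
        np.array(gene_ids, dtype=object),
        np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        layer="normalized",
    )


class TestModuleScore:
    def test_constant_matrix_scores_exactly_zero(self):
        m = normalized(np.full((10, 60), 2.5))
        gs = GeneSet("S", ("G0", "G1", "G2"))
        res = module_score(m, gs, n_bins=5, n_ctrl=10, seed=0)
        np.testing.assert_array_equal(res.scores.to_numpy(), 0.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        m = normalized(rng.uniform(0, 3, size=(20, 100)))
        gs = GeneSet("S", tuple(f"G{j}" for j in range(5)))
        a = module_score(m, gs, seed=7, n_bins=10).scores
        b = module_score(m, gs, seed=7, n_bins=10).scores
        pd.testing.assert_series_equal(a, b)

    def test_unbiased_for_random_gene_sets(self):
        # a gene set drawn from the control pool itself should score ~0
        rng = np.random.default_rng(1)
        m = normalized(rng.gamma(2, 1, size=(50, 200)))
        means = []
        for s in range(30):
            genes = tuple(f"G{j}" for j in rng.choice(200, 8, replace=False))
            res = module_score(m, GeneSet(f"S{s}", genes), n_bins=10,
                               n_ctrl=50, seed=s)
            means.append(res.scores.mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) <= 3 * se + 1e-3

    def test_planted_signature_cluster_scores_highest(self):
        rng = np.random.default_rng(2)
        n_cells, n_genes = 200, 300
        X = rng.gamma(2, 0.5, size=(n_cells, n_genes))
        clusters = np.repeat([0, 1, 2, 3], 50)
        set_idx = np.arange(10)
        X[np.ix_(clusters == 2, set_idx)] *= 4
        m = normalized(X)
        gs = GeneSet("S", tuple(f"G{j}" for j in set_idx))
        res = module_score(m, gs, seed=0)
        per_cluster = res.scores.groupby(clusters).mean()
        assert per_cluster.idxmax() == 2

    def test_absent_genes_warned_and_dropped(self):
        m = normalized(np.random.default_rng(0).uniform(size=(10, 50)))
        gs = GeneSet("S", ("G0", "NOT_THERE"))
        with pytest.warns(UserWarning, match="absent"):
            module_score(m, gs, n_bins=5)

    def test_too_many_bins_rejected(self):
        m = normalized(np.ones((5, 10)))
        with pytest.raises(ValueError, match="n_bins"):
            module_score(m, GeneSet("S", ("G0",)), n_bins=11)


class TestActivityScores:
    def test_hand_computed_two_cluster_example(self):
        # single-gene set, cluster A higher: mid-ranks 2 and 1 of K=2
        # -> percentiles (2-0.5)/2 = 0.75 and (1-0.5)/2 = 0.25 -> +-0.25
        counts = np.array([[10, 5], [10, 5], [2, 5], [2, 5]])
        clusters = np.array(["A", "A", "B", "B"])
        m = raw_matrix(counts)
        res = activity_scores(m, clusters, [GeneSet("S", ("G0",))])
        assert res.loc["A", "S"] == pytest.approx(0.25)
        assert res.loc["B", "S"] == pytest.approx(-0.25)

    def test_all_tied_clusters_score_zero(self):
        counts = np.tile(np.array([[3, 1, 4]]), (6, 1))
        clusters = np.repeat(["A", "B", "C"], 2)
        res = activity_scores(m := raw_matrix(counts), clusters,
                              [GeneSet("S", ("G0", "G1"))])
        np.testing.assert_allclose(res["S"], 0.0, atol=1e-12)

    def test_bounds_hold_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.integers(2, 6)
            counts = rng.poisson(2, size=(k * 3, 8))
            clusters = np.repeat(np.arange(k), 3)
            sets = [GeneSet("S", tuple(f"G{j}" for j in range(4)))]
            res = activity_scores(raw_matrix(counts), clusters, sets)
            assert (res["S"].abs() <= 0.5 + 1e-12).all()

    def test_scores_sum_to_zero_for_distinct_values(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 100, size=(8, 6))
        clusters = np.repeat(["A", "B", "C", "D"], 2)
        res = activity_scores(raw_matrix(counts), clusters,
                              [GeneSet("S", tuple(f"G{j}" for j in range(6)))])
        assert res["S"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_set_without_matrix_genes_warned_and_absent(self):
        counts = np.ones((4, 3), dtype=int)
        with pytest.warns(UserWarning, match="no genes"):
            res = activity_scores(raw_matrix(counts), ["A", "A", "B", "B"],
                                  [GeneSet("S", ("NOPE",))])
        assert "S" not in res.columns


class TestMetabolicFraction:
    def test_simple_ratio(self, basic_annotation):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [5, 95, 7]  # metabolic 5, other coding 95, non-coding 7
        m = raw_matrix(counts)
        ann = basic_annotation(m.gene_ids, metabolic={"G0"}, non_coding={"G2"})
        frac = metabolic_fraction(m, ann, per="cell")
        assert frac.iloc[0] == pytest.approx(0.05)

    def test_no_metabolic_expression_gives_zero(self, basic_annotation):
        counts = np.array([[0, 10]])
        m = raw_matrix(counts)
        ann = basic_annotation(m.gene_ids, metabolic={"G0"})
        assert metabolic_fraction(m, ann, per="cell").iloc[0] == 0.0

    def test_scale_invariance(self, basic_annotation):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(5, 10)) + 1
        ann = basic_annotation([f"G{j}" for j in range(10)],
                               metabolic={"G0", "G1"})
        a = metabolic_fraction(raw_matrix(counts), ann, per="cell")
        b = metabolic_fraction(raw_matrix(counts * 2), ann, per="cell")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_sample_fraction_is_count_weighted_cell_mean(self, basic_annotation):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, size=(6, 8)) + 1
        ann = basic_annotation([f"G{j}" for j in range(8)],
                               metabolic={"G0", "G3"})
        m = raw_matrix(counts)
        samples = np.array(["s1"] * 6)
        per_cell = metabolic_fraction(m, ann, per="cell")
        per_sample = metabolic_fraction(m, ann, per="sample", samples=samples)
        coding = counts.sum(axis=1)  # all genes coding here
        weighted = (per_cell * coding).sum() / coding.sum()
        assert per_sample.loc["s1"] == pytest.approx(weighted, abs=1e-12)

    def test_zero_coding_counts_reported_missing(self, basic_annotation):
        counts = np.array([[0, 4]])
        m = raw_matrix(counts)
        ann = basic_annotation(m.gene_ids, non_coding={"G0", "G1"})
        assert np.isnan(metabolic_fraction(m, ann, per="cell").iloc[0])

    def test_metabolic_outside_coding_warned_and_intersected(self, basic_annotation):
        counts = np.array([[5, 10]])
        m = raw_matrix(counts)
        ann = basic_annotation(m.gene_ids, metabolic={"G0"}, non_coding={"G0"})
        with pytest.warns(UserWarning, match="not protein-coding"):
            frac = metabolic_fraction(m, ann, per="cell")
        assert frac.iloc[0] == 0.0


def paired_design(n_pairs, n_unpaired0=0, n_unpaired1=0):
    rows = []
    for i in range(n_pairs):
        rows.append((f"s{i}i", f"p{i}", "indolent"))
        rows.append((f"s{i}a", f"p{i}", "active"))
    for i in range(n_unpaired0):
        rows.append((f"u{i}i", f"u{i}", "indolent"))
    for i in range(n_unpaired1):
        rows.append((f"u{i}a", f"v{i}", "active"))
    df = pd.DataFrame(rows, columns=["sample", "patient", "timepoint"])
    return df.set_index("sample")


class TestSampleMeanPermutationTest:
    def test_identical_conditions_give_p_near_one(self):
        design = paired_design(5)
        values = pd.Series(1.0, index=design.index)
        p = sample_mean_permutation_test(values, design, B=500, seed=0)
        assert p > 0.99

    def test_matches_exhaustive_sign_flip_on_fully_paired_design(self):
        rng = np.random.default_rng(5)
        design = paired_design(8)
        values = pd.Series(rng.normal(0, 1, size=16), index=design.index)
        values[design["timepoint"] == "active"] += 0.8

        tp = design["timepoint"].to_numpy()
        vals = values.to_numpy()

        def stat(flips):
            v = vals.copy()
            lab = tp == "active"
            for i, f in enumerate(flips):
                if f:
                    lab[2 * i], lab[2 * i + 1] = lab[2 * i + 1], lab[2 * i]
            return v[lab].mean() - v[~lab].mean()

        obs = stat([False] * 8)
        exceed = sum(
            abs(stat(flips)) >= abs(obs) - 1e-12
            for flips in itertools.product([False, True], repeat=8)
        )
        p_exact = exceed / 256
        B = 20_000
        p_mc = sample_mean_permutation_test(values, design, B=B, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / B

    def test_type_one_error_for_mixed_design(self):
        # 6 paired patients + 4 unpaired samples, null data
        rng = np.random.default_rng(6)
        design = paired_design(6, n_unpaired0=2, n_unpaired1=2)
        rejections = 0
        n_sim = 300
        for s in range(n_sim):
            values = pd.Series(rng.normal(size=len(design)), index=design.index)
            p = sample_mean_permutation_test(values, design, B=400, seed=s)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_unpairable_design_rejected(self):
        design = paired_design(0, n_unpaired0=1, n_unpaired1=1)
        values = pd.Series([1.0, 2.0], index=design.index)
        with pytest.raises(ValueError, match="unpaired"):
            sample_mean_permutation_test(values, design, B=100)


class TestOrientPseudotime:
    def test_correctly_oriented_input_only_rescaled(self):
        pt = np.array([0.0, 1.0, 2.0, 3.0])
        tp = np.array(["indolent", "indolent", "active", "active"])
        out = orient_pseudotime(pt, tp)
        np.testing.assert_allclose(out, [0, 1 / 3, 2 / 3, 1])

    def test_reversed_input_flipped(self):
        pt = np.array([3.0, 2.0, 1.0, 0.0])
        tp = np.array(["indolent", "indolent", "active", "active"])
        out = orient_pseudotime(pt, tp)
        np.testing.assert_allclose(out, [0, 1 / 3, 2 / 3, 1])

    def test_orientation_is_involution(self):
        rng = np.random.default_rng(7)
        pt = rng.uniform(0, 10, 50)
        tp = np.where(rng.random(50) < 0.5, "indolent", "active")
        once = orient_pseudotime(pt, tp)
        twice = orient_pseudotime(once, tp)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_constant_input_gives_half_with_warning(self):
        pt = np.ones(4)
        tp = np.array(["indolent", "active", "indolent", "active"])
        with pytest.warns(UserWarning, match="constant"):
            out = orient_pseudotime(pt, tp)
        np.testing.assert_array_equal(out, 0.5)

    def test_missing_timepoint_rejected(self):
        with pytest.raises(ValueError, match="active"):
            orient_pseudotime(np.arange(3), ["indolent"] * 3)
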