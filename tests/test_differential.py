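"""Normalization, BH correction, NB Wald differential expression, TE and
the differential-TE z-test, and the protein t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import translatome as tl
from translatome.differential import benjamini_hochberg


def bh_brute_force(p):
    """Step-up BH by direct definition: q_i = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = running
    return q


class TestBenjaminiHochberg:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100)
    )
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(
            benjamini_hochberg(pvals), bh_brute_force(pvals), atol=1e-12
        )

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestNormalization:
    def test_doubled_sample_has_double_size_factor(self, count_matrix_factory):
        rng = np.random.default_rng(2)
        base = rng.integers(10, 1000, size=50)
        cm = count_matrix_factory(
            np.column_stack([base, 2 * base]), conditions=("WT", "R98S")
        )
        sf, norm = tl.normalize_counts(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        np.testing.assert_allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_identical_samples_get_equal_factors(self, count_matrix_factory):
        base = np.arange(1, 41)
        cm = count_matrix_factory(np.column_stack([base] * 4))
        sf, _ = tl.normalize_counts(cm)
        np.testing.assert_allclose(sf, sf.iloc[0])

    def test_all_zero_gene_universe_rejected(self, count_matrix_factory):
        cm = count_matrix_factory([[0, 5, 0, 3], [2, 0, 1, 0]])
        with pytest.raises(ValueError, match="filter"):
            tl.normalize_counts(cm)


def simulated_null(seed, n_genes=2000, mean=200.0, dispersion=0.05):
    cfg = tl.SimulationConfig(seed=seed, n_genes=n_genes, nb_dispersion=dispersion)
    truth = tl.simulate_truth(cfg, 0, 0, 0, 0, 0, plant_marker=False)
    truth["mean_expression"] = mean
    return tl.simulate_counts(truth, cfg), truth


class TestDifferentialExpression:
    def test_identical_columns_are_null(self, count_matrix_factory):
        base = np.arange(5, 45)
        cm = count_matrix_factory(np.column_stack([base] * 6),
                                  conditions=("WT",) * 3 + ("R98S",) * 3)
        de = tl.differential_expression(cm)
        np.testing.assert_allclose(de.log2fc, 0.0)
        np.testing.assert_allclose(de.p, 1.0)

    def test_planted_four_fold_change_detected(self):
        cfg = tl.SimulationConfig(seed=11, n_genes=2000, nb_dispersion=0.01)
        truth = tl.simulate_truth(
            cfg, 30, 30, 0, 0, 0, mrna_log2fc_range=(2.0, 2.0), plant_marker=False
        )
        truth["mean_expression"] = 500.0
        mrna, _, _ = tl.simulate_counts(truth, cfg)
        de = tl.differential_expression(mrna)
        planted = truth.index[truth.true_mrna_log2fc != 0]
        assert (de.loc[planted, "fdr"] < 0.1).mean() >= 0.95

    def test_log2fc_estimate_unbiased_at_high_counts(self):
        cfg = tl.SimulationConfig(seed=12, n_genes=2000, nb_dispersion=0.05)
        # balanced up/down so median-of-ratios normalization is unbiased
        truth = tl.simulate_truth(
            cfg, 100, 100, 0, 0, 0, mrna_log2fc_range=(1.0, 1.0), plant_marker=False
        )
        truth["mean_expression"] = 500.0
        mrna, _, _ = tl.simulate_counts(truth, cfg)
        de = tl.differential_expression(mrna)
        planted = truth.index[truth.true_mrna_log2fc != 0]
        signed = de.loc[planted, "log2fc"] * np.sign(truth.loc[planted,
                                                              "true_mrna_log2fc"])
        assert signed.mean() == pytest.approx(1.0, abs=0.05)

    def test_single_replicate_condition_rejected(self, count_matrix_factory):
        cm = count_matrix_factory(
            [[10, 12, 11], [20, 18, 25]], conditions=("WT", "WT", "R98S")
        )
        with pytest.raises(ValueError, match="replicate"):
            tl.differential_expression(cm)

    def test_fdr_dominates_p(self):
        (mrna, _, _), _ = simulated_null(3, n_genes=500)
        de = tl.differential_expression(mrna)
        assert (de.fdr >= de.p - 1e-12).all()


class TestConsistentDe:
    @staticmethod
    def result_table(fdr, lfc):
        return pd.DataFrame({"log2fc": [lfc], "fdr": [fdr]}, index=["g"])

    def test_rule_enumeration(self):
        sig_up = self.result_table(0.01, 1.0)
        sig_down = self.result_table(0.01, -1.0)
        ns_up = self.result_table(0.5, 1.0)
        cases = [
            ([sig_up, sig_up, sig_up], ({"g"}, set())),
            ([sig_down, sig_down, sig_down], (set(), {"g"})),
            ([sig_up, sig_up, ns_up], (set(), set())),
            ([sig_up, sig_up, sig_down], (set(), set())),
        ]
        for tables, expected in cases:
            assert tl.consistent_de(tables) == expected

    def test_requires_two_datasets(self):
        with pytest.raises(ValueError):
            tl.consistent_de([self.result_table(0.01, 1.0)])


class TestTranslationEfficiency:
    def test_te_ratio_closed_form(self, count_matrix_factory):
        rpf = count_matrix_factory(np.full((3, 4), 50))
        mrna = count_matrix_factory(np.full((3, 4), 25))
        te = tl.compute_te(rpf, mrna, pseudocount=0.0)
        np.testing.assert_allclose(te.to_numpy(), 2.0)

    def test_zero_counts_give_unit_te(self, count_matrix_factory):
        rpf = count_matrix_factory([[0, 0, 0, 0], [50, 50, 50, 50]])
        mrna = count_matrix_factory([[0, 0, 0, 0], [50, 50, 50, 50]])
        te = tl.compute_te(rpf, mrna, pseudocount=0.5)
        np.testing.assert_allclose(te.loc["g0"], 1.0)

    def test_te_invariant_to_uniform_depth_doubling(self, count_matrix_factory):
        rng = np.random.default_rng(5)
        base_r = rng.integers(20, 500, size=(30, 4))
        base_m = rng.integers(20, 500, size=(30, 4))
        te1 = tl.compute_te(count_matrix_factory(base_r), count_matrix_factory(base_m),
                            pseudocount=0.0)
        te2 = tl.compute_te(count_matrix_factory(2 * base_r),
                            count_matrix_factory(2 * base_m), pseudocount=0.0)
        np.testing.assert_allclose(te1.to_numpy(), te2.to_numpy(), rtol=1e-10)

    def test_identical_conditions_are_null(self, count_matrix_factory):
        rng = np.random.default_rng(6)
        r = rng.integers(50, 500, size=(40, 3))
        m = rng.integers(50, 500, size=(40, 3))
        rpf = count_matrix_factory(np.column_stack([r, r]),
                                   conditions=("WT",) * 3 + ("R98S",) * 3)
        mrna = count_matrix_factory(np.column_stack([m, m]),
                                    conditions=("WT",) * 3 + ("R98S",) * 3)
        te = tl.differential_te(rpf, mrna)
        np.testing.assert_allclose(te.z, 0.0, atol=1e-9)
        np.testing.assert_allclose(te.fdr, 1.0)

    def test_label_swap_flips_sign(self):
        cfg = tl.SimulationConfig(seed=14, n_genes=300, nb_dispersion=0.02)
        truth = tl.simulate_truth(cfg, 0, 0, 30, 0, 0, plant_marker=False)
        truth["mean_expression"] = 300.0
        mrna, rpf, _ = tl.simulate_counts(truth, cfg)
        fwd = tl.differential_te(rpf, mrna, reference="WT")
        rev = tl.differential_te(rpf, mrna, reference="R98S")
        np.testing.assert_allclose(fwd.z, -rev.z, rtol=1e-8)
        np.testing.assert_allclose(fwd.log2_te_ratio, -rev.log2_te_ratio, rtol=1e-8)

    def test_zero_coverage_gene_directs_to_filter(self, count_matrix_factory):
        rpf = count_matrix_factory(
            np.vstack([[0] * 6, np.full((3, 6), 50)]),
            conditions=("WT",) * 3 + ("R98S",) * 3,
        )
        mrna = count_matrix_factory(
            np.full((4, 6), 50), conditions=("WT",) * 3 + ("R98S",) * 3
        )
        with pytest.raises(ValueError, match="filter_low_coverage"):
            tl.differential_te(rpf, mrna)


class TestProteinDifferential:
    @staticmethod
    def make_table(wt, mut, genes=None):
        wt, mut = np.atleast_2d(wt), np.atleast_2d(mut)
        genes = genes or [f"g{i}" for i in range(wt.shape[0])]
        samples = [f"WT_{i}" for i in range(wt.shape[1])] + [
            f"R98S_{i}" for i in range(mut.shape[1])
        ]
        values = pd.DataFrame(np.hstack([wt, mut]), index=genes, columns=samples)
        conditions = pd.Series(["WT"] * wt.shape[1] + ["R98S"] * mut.shape[1],
                               index=samples)
        return tl.ProteinTable(values, conditions)

    def test_identical_groups_null(self):
        table = self.make_table([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        result = tl.protein_differential(table)
        assert result.log2fc.iloc[0] == 0.0
        assert result.p.iloc[0] == 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        table = self.make_table(rng.normal(size=(10_000, 3)),
                                rng.normal(size=(10_000, 3)))
        result = tl.protein_differential(table)
        assert stats.kstest(result.p, "uniform").pvalue > 0.01

    def test_planted_marker_magnitude_flagged(self):
        rng = np.random.default_rng(9)
        wt = rng.normal(0.0, 0.3, size=(1, 3))
        mut = rng.normal(np.log2(4.7), 0.3, size=(1, 3))
        result = tl.protein_differential(self.make_table(wt, mut))
        assert bool(result.significant.iloc[0])

    def test_zero_variance_unequal_means_uses_floor(self):
        table = self.make_table([[1.0, 1.0, 1.0]], [[2.0, 2.0, 2.0]])
        result = tl.protein_differential(table)
        assert result.p.iloc[0] < 0.01
        assert np.isfinite(result.t.iloc[0])
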