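"""Concordance classification, variance-explained regression, fold-change
correlation and sample-level PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest

import translatome as tl


def de_table(gene, status, fdr_threshold=0.1):
    lfc = {"up": 1.0, "down": -1.0, "ns": 0.5}[status]
    fdr = 0.01 if status in ("up", "down") else 0.5
    return pd.DataFrame({"log2fc": [lfc], "fdr": [fdr]}, index=[gene])


def expected_category(mrna_status, te_status, protein_sign, require_sign=True):
    """Independent truth table for the classifier."""

    def supports(status):
        if status == "ns":
            return False
        if not require_sign:
            return True
        return (status == "up") == (protein_sign > 0)

    m, t = supports(mrna_status), supports(te_status)
    if m and t:
        return "both"
    if m:
        return "mrna_only"
    if t:
        return "te_only"
    return "unexplained"


class TestClassifier:
    @pytest.mark.parametrize("mrna_status", ["up", "down", "ns"])
    @pytest.mark.parametrize("te_status", ["up", "down", "ns"])
    @pytest.mark.parametrize("protein_sign", [1, -1])
    @pytest.mark.parametrize("require_sign", [True, False])
    def test_agrees_with_truth_table(self, mrna_status, te_status, protein_sign,
                                     require_sign):
        proteins = pd.DataFrame(
            {"log2fc": [protein_sign * 2.0], "p": [0.001]}, index=["g"]
        )
        records, summary = tl.classify_protein_changes(
            proteins,
            {"mrna": de_table("g", mrna_status)},
            {"te": de_table("g", te_status)},
            require_sign=require_sign,
        )
        assert summary.n_total == 1
        assert records.loc["g", "category"] == expected_category(
            mrna_status, te_status, protein_sign, require_sign
        )

    def test_any_vs_all_mrna_rule(self):
        proteins = pd.DataFrame({"log2fc": [1.0], "p": [0.001]}, index=["g"])
        de = {"d1": de_table("g", "up"), "d2": de_table("g", "ns")}
        te = {"te": de_table("g", "ns")}
        any_rec, _ = tl.classify_protein_changes(proteins, de, te, mrna_rule="any")
        all_rec, _ = tl.classify_protein_changes(proteins, de, te, mrna_rule="all")
        assert any_rec.loc["g", "category"] == "mrna_only"
        assert all_rec.loc["g", "category"] == "unexplained"

    def test_te_union_over_methods(self):
        proteins = pd.DataFrame({"log2fc": [1.0], "p": [0.001]}, index=["g"])
        te = {"footprinting": de_table("g", "ns"), "polysomal": de_table("g", "up")}
        records, _ = tl.classify_protein_changes(
            proteins, {"mrna": de_table("g", "ns")}, te
        )
        assert records.loc["g", "category"] == "te_only"

    def test_nonsignificant_proteins_ignored(self):
        proteins = pd.DataFrame({"log2fc": [1.0, 1.0], "p": [0.5, 0.001]},
                                index=["g_ns", "g_sig"])
        records, summary = tl.classify_protein_changes(
            proteins,
            {"mrna": de_table("g_sig", "up")},
            {"te": de_table("g_sig", "ns")},
        )
        assert summary.n_total == 1
        assert "g_ns" not in records.index

    def test_categories_partition_and_percentages_sum(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(60)]
        proteins = pd.DataFrame(
            {"log2fc": rng.normal(size=60), "p": rng.uniform(0, 0.02, size=60)},
            index=genes,
        )
        de = pd.DataFrame(
            {"log2fc": rng.normal(size=60), "fdr": rng.uniform(0, 0.3, size=60)},
            index=genes,
        )
        te = pd.DataFrame(
            {"log2fc": rng.normal(size=60), "fdr": rng.uniform(0, 0.3, size=60)},
            index=genes,
        )
        records, summary = tl.classify_protein_changes(proteins, {"m": de}, {"t": te})
        assert sum(summary.counts.values()) == summary.n_total == len(records)
        assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=0.1)

    def test_empty_significant_set(self):
        proteins = pd.DataFrame({"log2fc": [1.0], "p": [0.9]}, index=["g"])
        records, summary = tl.classify_protein_changes(
            proteins, {"m": de_table("g", "up")}, {"t": de_table("g", "ns")}
        )
        assert summary.n_total == 0
        assert records.empty


class TestExplainVariance:
    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 2))
        y = 0.3 + 1.2 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(0, 0.5, size=50)
        predictors = pd.DataFrame(X, columns=["mrna", "te"])
        report = tl.explain_variance(pd.Series(y), predictors)
        design = np.column_stack([np.ones(50), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(report.coefficients.to_numpy(), beta, atol=1e-10)
        resid = y - design @ beta
        r2 = 1 - resid.var() / y.var()
        assert report.r_squared == pytest.approx(r2, abs=1e-10)

    def test_exact_linear_combination_gives_unit_r2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = 2.0 * X[:, 0] + 3.0 * X[:, 1]
        report = tl.explain_variance(
            pd.Series(y), pd.DataFrame(X, columns=["a", "b"])
        )
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_predictors_give_near_zero_r2(self):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=5000))
        X = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["a", "b"])
        assert tl.explain_variance(y, X).r_squared < 0.01

    def test_collinear_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        y = pd.Series(x + rng.normal(0, 0.1, size=40))
        X = pd.DataFrame({"a": x, "a_copy": 2 * x})
        with pytest.warns(UserWarning, match="collinear"):
            report = tl.explain_variance(y, X)
        assert report.predictors == ("a",)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            tl.explain_variance(pd.Series([1.0, 2.0]),
                                pd.DataFrame({"a": [1.0, 2.0]}))


class TestFoldChangeCorrelation:
    def test_perfect_correlation(self):
        a = pd.Series(np.arange(10, dtype=float))
        assert tl.fold_change_correlation(a, a)[0] == pytest.approx(1.0)
        assert tl.fold_change_correlation(a, -a)[0] == pytest.approx(-1.0)

    def test_pairwise_missing_excluded(self):
        a = pd.Series([1.0, 2.0, 3.0, np.nan, 5.0])
        b = pd.Series([1.0, 2.0, 3.0, 4.0, np.nan])
        r, n = tl.fold_change_correlation(a, b)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        a = pd.Series([1.0, 1.0, 1.0, 1.0])
        b = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero variance"):
            r, _ = tl.fold_change_correlation(a, b)
        assert np.isnan(r)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(11)
        rho, n = 0.76, 10_645
        cov = [[1.0, rho], [rho, 1.0]]
        draws = rng.multivariate_normal([0, 0], cov, size=n)
        r, n_used = tl.fold_change_correlation(
            pd.Series(draws[:, 0]), pd.Series(draws[:, 1])
        )
        assert n_used == n
        assert r == pytest.approx(rho, abs=0.01)  # ~2.4 Fisher-z SEs


class TestSamplePca:
    def test_conditions_separate_on_pc1(self):
        cfg = tl.SimulationConfig(seed=15, n_genes=800, nb_dispersion=0.01)
        truth = tl.simulate_truth(cfg, 80, 80, 0, 0, 0, plant_marker=False)
        _, rpf, _ = tl.simulate_counts(truth, cfg)
        _, norm = tl.normalize_counts(rpf)
        coords, _ = tl.sample_pca(norm)
        wt = coords.loc[[s for s in coords.index if s.startswith("WT")], "PC1"]
        mut = coords.loc[[s for s in coords.index if s.startswith("R98S")], "PC1"]
        assert wt.max() < mut.min() or mut.max() < wt.min()

    def test_variance_fractions_sum_below_one(self, count_matrix_factory):
        rng = np.random.default_rng(12)
        cm = count_matrix_factory(rng.integers(10, 400, size=(100, 4)))
        _, norm = tl.normalize_counts(cm)
        _, explained = tl.sample_pca(norm, n_components=3)
        assert explained.sum() <= 1.0 + 1e-9

    def test_duplicated_sample_is_coincident(self, count_matrix_factory):
        rng = np.random.default_rng(13)
        base = rng.integers(10, 400, size=(100, 3))
        arr = np.column_stack([base, base[:, 0]])
        cm = count_matrix_factory(arr)
        norm = cm.counts.astype(float)  # skip size factors: duplicate is exact
        coords, _ = tl.sample_pca(norm)
        np.testing.assert_allclose(
            coords.iloc[0].to_numpy(), coords.iloc[3].to_numpy(), atol=1e-8
        )

    def test_too_few_samples_rejected(self, count_matrix_factory):
        cm = count_matrix_factory([[1, 2], [3, 4]], conditions=("WT", "R98S"))
        with pytest.raises(ValueError):
            tl.sample_pca(cm.counts.astype(float))
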