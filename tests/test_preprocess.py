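"""Expression preprocessing, QC and module construction."""

import numpy as np
import pytest
from scipy.stats import norm

from transpco import (CovariateMatrix, ExpressionMatrix, GeneAnnotation,
                      detect_coexpression_modules, filter_genes, genotype_qc,
                      load_gene_sets, quantile_then_inverse_normal,
                      regress_out_covariates, tpm_normalize)
from transpco.preprocess import hwe_pvalue
from transpco.synthetic import generate_cohort, make_block_sigma

import pandas as pd


def expr(values, stage="counts", genes=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    genes = genes or [f"g{j + 1}" for j in range(g)]
    return ExpressionMatrix([f"s{i + 1}" for i in range(n)], genes, values, stage)


class TestTPM:
    def test_equal_length_normalised_rates_split_evenly(self):
        x = tpm_normalize(expr([[10, 20]]), {"g1": 1000, "g2": 2000})
        np.testing.assert_allclose(x.values, [[500_000, 500_000]])

    def test_single_gene_gets_everything(self):
        x = tpm_normalize(expr([[7]]), {"g1": 500})
        np.testing.assert_allclose(x.values, [[1e6]])

    def test_row_sums_conserved(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(5, 4)).astype(float) + 1
        lengths = {f"g{j + 1}": int(l) for j, l in
                   enumerate(rng.integers(500, 5000, size=4))}
        x = tpm_normalize(expr(counts), lengths)
        np.testing.assert_allclose(x.values.sum(axis=1), 1e6, rtol=1e-9)

    def test_zero_rate_sample_named(self):
        with pytest.raises(ValueError, match="s2"):
            tpm_normalize(expr([[1, 1], [0, 0]]), {"g1": 100, "g2": 100})

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="g2"):
            tpm_normalize(expr([[1, 1]]), {"g1": 100, "g2": 0})


class TestNormalisation:
    def test_permuted_samples_equalised(self):
        a = [3.0, 1.0, 5.0, 2.0]
        x = quantile_then_inverse_normal(expr([a, a[::-1]], stage="tpm"))
        # both samples carry the same multiset of values after step 1+2
        assert sorted(np.round(x.values[0], 9)) == sorted(np.round(x.values[1], 9))

    def test_gene_columns_standard_normal_quantiles(self):
        # tie-free gene columns land exactly on the N inverse-normal quantiles
        rng = np.random.default_rng(1)
        x = quantile_then_inverse_normal(
            expr(rng.lognormal(size=(4, 30)), stage="tpm"))
        expected = norm.ppf((np.arange(1, 5) - 0.5) / 4)
        n_exact = 0
        for j in range(len(x.gene_ids)):
            col = np.sort(x.values[:, j])
            if np.unique(np.round(col, 9)).size == 4:
                np.testing.assert_allclose(col, expected, atol=1e-9)
                n_exact += 1
        assert n_exact >= 10  # ties (shared within-sample ranks) affect a minority

    def test_moments_near_standard_normal(self):
        rng = np.random.default_rng(2)
        x = quantile_then_inverse_normal(
            expr(rng.lognormal(size=(100, 300)), stage="tpm"))
        assert np.max(np.abs(x.values.mean(axis=0))) < 0.02
        assert np.max(np.abs(x.values.std(axis=0) - 1.0)) < 0.05
        # symmetry of the rank-based construction
        assert np.max(np.abs(np.median(x.values, axis=0))) < 0.1

    def test_idempotence_up_to_rank_collisions(self):
        # re-applying the map preserves each gene's distribution and ranks up
        # to flips at exact rank collisions
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x1 = quantile_then_inverse_normal(
            expr(rng.lognormal(size=(50, 200)), stage="tpm"))
        x2 = quantile_then_inverse_normal(
            ExpressionMatrix(x1.sample_ids, x1.gene_ids, x1.values, "tpm"))
        for j in range(len(x1.gene_ids)):
            assert np.mean(np.abs(np.sort(x1.values[:, j]) -
                                  np.sort(x2.values[:, j]))) < 0.05
            assert spearmanr(x1.values[:, j], x2.values[:, j]).statistic > 0.98

    def test_constant_gene_dropped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            x = quantile_then_inverse_normal(
                expr([[1.0, 5.0, 2.0], [1.0, 7.0, 9.0], [1.0, 6.0, 4.0]],
                     stage="tpm"))
        # the degenerate column is every sample's minimum, so after
        # quantile normalisation it is constant and removed
        assert "g1" not in x.gene_ids
        assert {"g2", "g3"} <= set(x.gene_ids)


class TestResiduals:
    def test_intercept_only_centres(self):
        rng = np.random.default_rng(4)
        x = expr(rng.normal(2.0, 1.0, size=(50, 3)), stage="normalized")
        cov = CovariateMatrix(x.sample_ids, [], np.empty((50, 0)))
        r = regress_out_covariates(x, cov)
        np.testing.assert_allclose(r.values, x.values - x.values.mean(axis=0),
                                   atol=1e-10)

    def test_gene_equal_to_covariate_vanishes(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=100)
        x = expr(np.column_stack([c, rng.normal(size=100)]), stage="normalized")
        cov = CovariateMatrix(x.sample_ids, ["c1"], c[:, None])
        r = regress_out_covariates(x, cov)
        np.testing.assert_allclose(r.values[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(6)
        C = rng.normal(size=(200, 3))
        x = expr(C @ rng.normal(size=(3, 4)) + rng.normal(size=(200, 4)),
                 stage="normalized")
        cov = CovariateMatrix(x.sample_ids, ["a", "b", "c"], C)
        r = regress_out_covariates(x, cov)
        assert np.max(np.abs(C.T @ r.values)) < 1e-8

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(7)
        c1 = rng.normal(size=500)
        e = rng.normal(size=500)
        x = expr((2.0 * c1 + e)[:, None], stage="normalized")
        cov = CovariateMatrix(x.sample_ids, ["c1"], c1[:, None])
        r = regress_out_covariates(x, cov)
        assert np.corrcoef(r.values[:, 0], e)[0, 1] > 0.99

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(8)
        c = rng.normal(size=30)
        cov = CovariateMatrix([f"s{i + 1}" for i in range(30)],
                              ["c1", "c2"], np.column_stack([c, 2 * c]))
        x = expr(rng.normal(size=(30, 2)), stage="normalized")
        with pytest.raises(ValueError, match="c2"):
            regress_out_covariates(x, cov)

    def test_residualisation_preserves_planted_correlation(self):
        # block-correlated genes plus a shared covariate: removing the
        # covariate must leave the block correlation intact
        rng = np.random.default_rng(9)
        n = 600
        shared = rng.normal(size=n)
        sigma = make_block_sigma([6, 6], rho_within=0.6)
        L = np.linalg.cholesky(sigma.values)
        base = rng.normal(size=(n, 12)) @ L.T
        x = expr(base + 1.5 * shared[:, None], stage="normalized")
        cov = CovariateMatrix(x.sample_ids, ["shared"], shared[:, None])
        r = regress_out_covariates(x, cov)
        R = np.corrcoef(r.values, rowvar=False)
        assert abs(R[0, 1] - 0.6) < 0.1
        assert abs(R[0, 6]) < 0.15


class TestGeneFilters:
    ANN = [
        GeneAnnotation("proteinA", "chr1", 1, 100, "protein_coding", 1.0),
        GeneAnnotation("pseudoB", "chr1", 200, 300, "pseudogene", 1.0),
        GeneAnnotation("lincC", "chr2", 1, 100, "lincRNA", 0.8),
    ]

    def test_biotype_and_mappability_rules(self):
        assert filter_genes(self.ANN) == {"proteinA"}

    def test_empty_allowed_set(self):
        assert filter_genes(self.ANN, allowed_biotypes=frozenset()) == set()

    def test_relaxed_mappability_threshold(self):
        assert filter_genes(self.ANN, min_mappability=0.8) == {"proteinA", "lincC"}

    def test_unknown_biotype_excluded_with_warning(self, caplog):
        import logging

        ann = [GeneAnnotation("weird", "chr1", 1, 2, "mystery_type", 1.0)]
        with caplog.at_level(logging.WARNING):
            assert filter_genes(ann) == set()
        assert any("mystery_type" in r.message for r in caplog.records)


class TestGenotypeQC:
    def test_hwe_proportions_kept(self):
        # AA=810, Aa=180, aa=10 out of 1000 are exact HWE at p=0.9
        g = np.repeat([0.0, 1.0, 2.0], [810, 180, 10])
        df = pd.DataFrame({"snp1": g})
        kept, report = genotype_qc(df)
        assert "snp1" in kept.columns
        assert report.n_kept == 1
        assert hwe_pvalue(810, 180, 10) > 0.5

    def test_low_maf_dropped(self):
        rng = np.random.default_rng(10)
        good = rng.binomial(2, 0.3, size=1000).astype(float)
        rare = rng.binomial(2, 0.04, size=1000).astype(float)
        df = pd.DataFrame({"common": good, "rare": rare})
        kept, report = genotype_qc(df)
        assert list(kept.columns) == ["common"]
        assert report.n_dropped_maf == 1

    def test_missingness_dropped(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, size=1000).astype(float)
        g2 = g.copy()
        g2[:20] = np.nan  # 2% missing
        df = pd.DataFrame({"full": g, "gappy": g2})
        kept, report = genotype_qc(df)
        assert list(kept.columns) == ["full"]
        assert report.n_dropped_callrate == 1

    def test_hwe_violation_dropped(self):
        # all heterozygotes: maximal HWE violation
        g = np.ones(1000)
        df = pd.DataFrame({"het": g, "ok": np.repeat([0., 1., 2.], [490, 420, 90])})
        kept, report = genotype_qc(df)
        assert "het" not in kept.columns
        assert report.n_dropped_hwe == 1

    def test_all_dropped_raises_with_breakdown(self):
        df = pd.DataFrame({"rare": np.zeros(100)})
        df.iloc[0, 0] = 1.0
        with pytest.raises(ValueError, match="MAF"):
            genotype_qc(df)

    def test_exact_and_chisq_regimes_agree_at_moderate_counts(self):
        p_exact = hwe_pvalue(490, 420, 90)
        p_chi = hwe_pvalue(4900, 4200, 900)
        assert (p_exact < 0.05) == (p_chi < 0.05)


class TestModules:
    def _blocky(self, sizes, rho, n=300, seed=0, extra_indep=0):
        sigma = make_block_sigma(sizes, rho_within=rho)
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(sigma.values)
        V = rng.standard_normal((n, sigma.n_genes)) @ L.T
        if extra_indep:
            V = np.hstack([V, rng.standard_normal((n, extra_indep))])
        genes = [f"g{j + 1}" for j in range(V.shape[1])]
        return ExpressionMatrix([f"s{i+1}" for i in range(n)], genes, V, "residual")

    def test_two_planted_blocks_recovered(self):
        x = self._blocky([15, 15], rho=0.8)
        mods = detect_coexpression_modules(x)
        assert len(mods) == 2
        found = {frozenset(m.gene_ids) for m in mods}
        assert frozenset(f"g{j}" for j in range(1, 16)) in found
        assert frozenset(f"g{j}" for j in range(16, 31)) in found

    def test_independent_genes_stay_unclustered(self):
        rng = np.random.default_rng(12)
        x = ExpressionMatrix([f"s{i}" for i in range(200)],
                             [f"g{j}" for j in range(40)],
                             rng.standard_normal((200, 40)), "residual")
        assert detect_coexpression_modules(x) == []

    def test_block_below_minimum_size_not_reported(self):
        x = self._blocky([9], rho=0.8, extra_indep=20)
        assert detect_coexpression_modules(x, min_module_size=10) == []

    def test_permutation_equivariance(self):
        x = self._blocky([12, 12], rho=0.7, seed=13)
        rng = np.random.default_rng(14)
        perm = rng.permutation(len(x.gene_ids))
        xp = ExpressionMatrix(x.sample_ids, [x.gene_ids[i] for i in perm],
                              x.values[:, perm], "residual")
        m1 = {frozenset(m.gene_ids) for m in detect_coexpression_modules(x)}
        m2 = {frozenset(m.gene_ids) for m in detect_coexpression_modules(xp)}
        assert m1 == m2

    def test_too_few_genes_raises(self):
        rng = np.random.default_rng(15)
        x = ExpressionMatrix(["s1", "s2", "s3"], ["g1", "g2"],
                             rng.standard_normal((3, 2)), "residual")
        with pytest.raises(ValueError):
            detect_coexpression_modules(x)


class TestGMT:
    def test_basic_sets(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg1\tg4\tg5\tg6\n")
        mods = load_gene_sets(p)
        assert [m.size for m in mods] == [3, 4]
        assert all(m.provenance == "gene_set" for m in mods)

    def test_duplicates_deduplicated(self, tmp_path, caplog):
        import logging

        p = tmp_path / "dup.gmt"
        p.write_text("setA\tdesc\tg1\tg1\tg2\n")
        with caplog.at_level(logging.WARNING):
            mods = load_gene_sets(p)
        assert mods[0].gene_ids == ("g1", "g2")

    def test_unannotated_genes_dropped_and_empty_sets_skipped(self, tmp_path):
        p = tmp_path / "ann.gmt"
        p.write_text("setA\tdesc\tg1\tgX\nsetB\tdesc\tgY\tgZ\n")
        ann = {"g1": None}
        mods = load_gene_sets(p, annotation=ann)
        assert len(mods) == 1
        assert mods[0].gene_ids == ("g1",)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("setA\tdesc\tg1\nonlyname\n")
        with pytest.raises(ValueError, match=":2"):
            load_gene_sets(p)
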