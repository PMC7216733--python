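import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from contrastseq import (
    adjust_bh,
    align_and_validate,
    build_design_matrix,
    estimate_common_dispersion,
    estimate_tagwise_dispersions,
    fit_gene_glm,
    generate_contrasts,
    lrt_contrast,
    pvalue_histogram,
    tmm_factors,
    top_degs,
    NBDifferentialModel,
)
from contrastseq.glm import _apl, _phi_grid, fit_glm_batch, nb_loglik
from contrastseq.simulate import SimulationSpec, simulate_counts
from conftest import make_design


TWO_GROUP_X = np.column_stack(
    [np.ones(8), np.repeat([0.0, 1.0], 4)]
)  # intercept + group
EQUAL_OFFSETS = np.zeros(8)


class TestGeneFit:
    def test_saturated_poisson_fit_is_exact(self):
        y = np.array([3.0, 7.0, 11.0, 2.0])
        x = np.eye(4)  # one coefficient per sample
        fit = fit_gene_glm(y, x, np.zeros(4), dispersion=0.0)
        np.testing.assert_allclose(fit.mu, y, rtol=1e-6)
        assert fit.deviance < 1e-8

    def test_matches_poisson_glm_oracle(self):
        y = np.array([5.0, 8.0, 6.0, 7.0, 15.0, 19.0, 13.0, 17.0])
        fit = fit_gene_glm(y, TWO_GROUP_X, EQUAL_OFFSETS, dispersion=0.0)
        oracle = sm.GLM(y, TWO_GROUP_X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)

    def test_intercept_only_equal_offsets_gives_sample_mean(self):
        y = np.array([4.0, 9.0, 2.0, 5.0, 10.0])
        fit = fit_gene_glm(y, np.ones((5, 1)), np.zeros(5), dispersion=0.3)
        np.testing.assert_allclose(fit.mu, np.full(5, y.mean()), rtol=1e-6)

    def test_all_zero_gene_hits_floor(self):
        y = np.zeros(6)
        fit = fit_gene_glm(y, np.ones((6, 1)), np.zeros(6), dispersion=0.1)
        assert fit.beta[0] == -50.0

    def test_nonfinite_design_rejected(self):
        x = np.ones((4, 1))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_gene_glm(np.ones(4), x, np.zeros(4))

    def test_batch_matches_single(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(20.0, size=(10, 8)).astype(float)
        beta, mu, dev, conv = fit_glm_batch(y, TWO_GROUP_X, EQUAL_OFFSETS, 0.1)
        for g in range(10):
            single = fit_gene_glm(y[g], TWO_GROUP_X, EQUAL_OFFSETS, 0.1)
            np.testing.assert_allclose(beta[g], single.beta, atol=1e-10)


class TestDispersion:
    @staticmethod
    def nb_counts(phi, n_genes, seed, mu_range=(50, 500)):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(*mu_range, size=(n_genes, 1)) * np.ones((1, 8))
        mu[:, 4:] *= rng.uniform(0.5, 2.0, size=(n_genes, 1))  # group effect
        if phi == 0:
            return rng.poisson(mu).astype(float)
        r = 1.0 / phi
        return rng.negative_binomial(r, r / (r + mu)).astype(float)

    def test_poisson_data_estimates_near_zero(self):
        y = self.nb_counts(0.0, 500, seed=1)
        est = estimate_common_dispersion(y, TWO_GROUP_X, EQUAL_OFFSETS)
        assert est <= 0.01

    def test_recovers_true_dispersion(self):
        y = self.nb_counts(0.1, 500, seed=2)
        est = estimate_common_dispersion(y, TWO_GROUP_X, EQUAL_OFFSETS)
        assert 0.07 <= est <= 0.13

    def test_single_gene_matches_grid_oracle(self):
        y = self.nb_counts(0.2, 1, seed=3)
        est = estimate_common_dispersion(y, TWO_GROUP_X, EQUAL_OFFSETS)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(10), 400))
        vals = [float(_apl(y, TWO_GROUP_X, EQUAL_OFFSETS, g)[0]) for g in grid]
        oracle = grid[int(np.argmax(vals))]
        assert abs(np.log(est) - np.log(oracle)) < 0.02

    def test_infinite_prior_df_returns_common(self):
        y = self.nb_counts(0.1, 40, seed=4)
        common = estimate_common_dispersion(y, TWO_GROUP_X, EQUAL_OFFSETS)
        tag = estimate_tagwise_dispersions(
            y, TWO_GROUP_X, EQUAL_OFFSETS, common, prior_df=np.inf
        )
        np.testing.assert_allclose(tag, common)

    def test_zero_prior_df_matches_per_gene_grid_oracle(self):
        y = self.nb_counts(0.1, 15, seed=5)
        tag = estimate_tagwise_dispersions(
            y, TWO_GROUP_X, EQUAL_OFFSETS, prior_df=0.0
        )
        grid = np.exp(np.linspace(np.log(1e-4), np.log(10), 300))
        apl = np.stack(
            [_apl(y, TWO_GROUP_X, EQUAL_OFFSETS, g) for g in grid], axis=1
        )
        oracle = grid[np.argmax(apl, axis=1)]
        np.testing.assert_allclose(np.log(tag), np.log(oracle), atol=0.05)

    def test_two_dispersion_groups_ordered(self):
        y_low = self.nb_counts(0.05, 150, seed=6)
        y_high = self.nb_counts(0.4, 150, seed=7)
        y = np.vstack([y_low, y_high])
        tag = estimate_tagwise_dispersions(y, TWO_GROUP_X, EQUAL_OFFSETS, prior_df=5.0)
        assert tag[:150].mean() < tag[150:].mean()

    def test_no_residual_df_rejected(self):
        with pytest.raises(ValueError, match="simpler model"):
            estimate_common_dispersion(np.ones((3, 4)), np.eye(4), np.zeros(4))


class TestLRT:
    @staticmethod
    def one_factor_glm():
        design = make_design(
            {"Geno": ["WT"] * 4 + ["Mut"] * 4}, ["Geno"],
            samples=[f"s{i}" for i in range(8)],
        )
        glm = build_design_matrix(design)
        return glm, generate_contrasts(glm)[0]

    def test_null_simulation_pvalues_uniform(self):
        glm, contrast = self.one_factor_glm()
        rng = np.random.default_rng(11)
        mu = rng.uniform(30, 300, size=(2000, 1)) * np.ones((1, 8))
        r = 1 / 0.1
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        res = lrt_contrast(y, glm, np.zeros(8), 0.1, contrast)
        ks = kstest(res.table["pvalue"], "uniform").statistic
        # 1% critical value of the one-sample KS statistic at n=2000
        assert ks < 1.63 / np.sqrt(2000)

    def test_constant_gene_balanced_design(self):
        glm, contrast = self.one_factor_glm()
        y = np.full((1, 8), 25.0)
        res = lrt_contrast(y, glm, np.zeros(8), 0.1, contrast)
        assert res.table["log2FC"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert res.table["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_poisson_lrt_matches_closed_form(self):
        # with equal offsets the Poisson group-means MLE is closed form
        glm, contrast = self.one_factor_glm()
        y = np.array([[12.0, 9.0, 15.0, 11.0, 25.0, 31.0, 22.0, 28.0]])
        res = lrt_contrast(y, glm, np.zeros(8), 0.0, contrast)
        y1, y2 = y[0, :4], y[0, 4:]
        ll = lambda v, m: np.sum(v * np.log(m) - m)
        lr_oracle = 2 * (
            ll(y1, y1.mean()) + ll(y2, y2.mean()) - ll(y[0], y[0].mean())
        )
        assert res.table["LR"].iloc[0] == pytest.approx(lr_oracle, abs=1e-6)

    def test_lr_invariant_to_contrast_scaling(self):
        # scaling the contrast changes the basis completion but not the test
        glm, contrast = self.one_factor_glm()
        rng = np.random.default_rng(2)
        y = rng.poisson(40, size=(5, 8)).astype(float)
        res1 = lrt_contrast(y, glm, np.zeros(8), 0.05, contrast)
        import copy

        scaled = copy.deepcopy(contrast)
        scaled.vector = -3.0 * scaled.vector
        res2 = lrt_contrast(y, glm, np.zeros(8), 0.05, scaled)
        np.testing.assert_allclose(
            res1.table["LR"], res2.table["LR"], atol=1e-6
        )

    def test_results_equal_under_gene_permutation(self):
        glm, contrast = self.one_factor_glm()
        rng = np.random.default_rng(3)
        y = rng.poisson(60, size=(40, 8)).astype(float)
        perm = rng.permutation(40)
        res = lrt_contrast(y, glm, np.zeros(8), 0.1, contrast)
        res_p = lrt_contrast(y[perm], glm, np.zeros(8), 0.1, contrast)
        np.testing.assert_allclose(
            res.table["pvalue"].to_numpy()[perm], res_p.table["pvalue"], rtol=1e-9
        )

    def test_zero_contrast_rejected(self):
        glm, contrast = self.one_factor_glm()
        import copy

        zero = copy.deepcopy(contrast)
        zero.vector = np.zeros_like(zero.vector)
        with pytest.raises(ValueError, match="zero"):
            lrt_contrast(np.ones((1, 8)), glm, np.zeros(8), 0.1, zero)


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.3]), [0.3])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2] * 5), [0.2] * 5)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, 1.5])


class TestPValueDiagnostic:
    def test_uniform_draws_pass(self):
        rng = np.random.default_rng(123)
        diag = pvalue_histogram(rng.random(2000))
        assert diag.uniform_tail
        assert diag.bin_counts.sum() == 2000

    def test_spike_near_one_flagged(self):
        p = np.concatenate([np.linspace(0, 1, 1600, endpoint=False), np.full(400, 0.99)])
        assert not pvalue_histogram(p).uniform_tail

    def test_all_zero_pvalues_flagged(self):
        assert not pvalue_histogram(np.zeros(2000)).uniform_tail


class TestTopDegs:
    @staticmethod
    def result_from(table: pd.DataFrame):
        from contrastseq.glm import ContrastTestResult
        from contrastseq.contrasts import Contrast
        from fractions import Fraction

        c = Contrast("[a-b]", "averaged", {("a",): Fraction(1), ("b",): Fraction(-1)})
        return ContrastTestResult(c, table, alpha=0.05)

    def test_order_and_truncation(self):
        table = pd.DataFrame(
            {
                "log2FC": [1.0, -3.0, 2.0, 0.5, 4.0],
                "LR": 0.0,
                "pvalue": [0.01, 0.001, 0.001, 0.02, 0.05],
                "adj_pvalue": [0.02, 0.01, 0.01, 0.03, 0.06],
                "is_deg": [True, True, True, True, False],
            },
            index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene"),
        )
        res = self.result_from(table)
        # tie at p=0.001 broken by |log2FC| (g2 over g3? |-3|>|2| -> g2 first)
        assert top_degs(res, 3) == ["g2", "g3", "g1"]
        assert top_degs(res, 50) == ["g2", "g3", "g1", "g4"]


class TestModelSurface:
    def test_fit_summary_and_power(self, table1_project):
        project, truth = table1_project
        norm = tmm_factors(project.counts)
        glm = build_design_matrix(project.design, True)
        model = NBDifferentialModel(project, glm, norm)
        res = model.fit()
        summary = res.summary()
        assert len(summary) == 7
        test = res.tests["[MatureLeaf-Root]"]
        true = truth.true_de_genes(test.contrast)
        called = set(test.degs.index)
        assert len(called & true) / len(true) >= 0.8
        assert str(res)  # renders without error
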