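import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from contrastseq import (
    CoexpressionGMM,
    NormalizationResult,
    arcsine_transform,
    expression_profiles,
    icl,
    select_model,
    tmm_factors,
)
from contrastseq.coexpression import _relabel_by_size
from contrastseq.simulate import simulate_coexpression
from conftest import make_counts


def unit_norm(cm, factors=None):
    f = np.ones(len(cm.sample_ids)) if factors is None else np.asarray(factors)
    return NormalizationResult("TMM", cm.sample_ids, f / np.exp(np.mean(np.log(f))), cm.library_sizes)


class TestProfiles:
    def test_single_sample_gene_is_unit_vector(self):
        cm = make_counts([[0, 90, 0], [100, 100, 100]])
        profiles, c0 = expression_profiles(cm, unit_norm(cm), mean_filter_cutoff=10)
        np.testing.assert_allclose(profiles.loc["g1"], [0.0, 1.0, 0.0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.integers(10, 500, size=(20, 6)))
        profiles, _ = expression_profiles(cm, unit_norm(cm), 1.0)
        np.testing.assert_allclose(profiles.sum(axis=1), 1.0, atol=1e-10)

    def test_low_mean_genes_go_to_cluster0(self):
        cm = make_counts([[500, 500], [3, 2], [0, 0]])
        profiles, c0 = expression_profiles(cm, unit_norm(cm), mean_filter_cutoff=50)
        assert set(c0) == {"g2", "g3"}
        assert profiles.index.tolist() == ["g1"]

    def test_toy_with_nonunit_factors(self):
        # effective sizes (200, 800) -> mean 500; normalized = y * 500/eff
        cm = make_counts([[40, 80]], samples=["a", "b"])
        norm = NormalizationResult("TMM", ["a", "b"], np.array([2.0, 0.5]),
                                   np.array([100.0, 1600.0]))
        profiles, _ = expression_profiles(cm, norm, mean_filter_cutoff=0)
        normed = np.array([40 * 500 / 200, 80 * 500 / 800])
        np.testing.assert_allclose(profiles.iloc[0], normed / normed.sum())

    def test_all_filtered_is_error(self):
        cm = make_counts([[1, 1], [2, 2]])
        with pytest.raises(ValueError, match="cutoff"):
            expression_profiles(cm, unit_norm(cm), mean_filter_cutoff=100)


class TestArcsine:
    def test_endpoints_and_midpoint(self):
        out = arcsine_transform(np.array([[0.0, 1.0, 0.5]]))
        np.testing.assert_allclose(out, [[0.0, np.pi / 2, np.pi / 4]])

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        p = rng.random((10, 5))
        v = arcsine_transform(p)
        np.testing.assert_allclose(np.sin(v) ** 2, p, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_transform(np.array([[1.5]]))


class TestGMM:
    @staticmethod
    def blobs(seed=0, n=200, d=4, sep=6.0):
        rng = np.random.default_rng(seed)
        centers = np.stack([np.zeros(d), np.full(d, sep / np.sqrt(d))])
        labels = rng.integers(0, 2, size=n)
        return centers[labels] + rng.normal(scale=1.0, size=(n, d)), labels

    def test_single_component_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 3))
        model = CoexpressionGMM(x).fit(K=1, n_inits=1, seed=0)
        np.testing.assert_allclose(model.means[0], x.mean(axis=0), atol=1e-8)
        emp_cov = np.cov(x.T, bias=True)
        np.testing.assert_allclose(model.covariances[0], emp_cov, atol=1e-4)
        np.testing.assert_allclose(model.posteriors, 1.0)
        assert model.entropy == 0.0
        assert icl(model, 50) == pytest.approx(model.bic)

    def test_loglik_monotone(self):
        x, _ = self.blobs()
        model = CoexpressionGMM(x).fit(K=3, n_inits=3, seed=1)
        hist = np.array(model.loglik_history)
        assert np.all(np.diff(hist) >= -1e-6 * (np.abs(hist[:-1]) + 1))

    def test_separated_blobs_recovered(self):
        x, labels = self.blobs(seed=3)
        model = CoexpressionGMM(x).fit(K=2, n_inits=5, seed=0)
        assert adjusted_rand_score(labels, model.hard_labels()) == 1.0

    def test_deterministic_under_seed(self):
        x, _ = self.blobs(seed=4)
        m1 = CoexpressionGMM(x).fit(K=3, n_inits=4, seed=9)
        m2 = CoexpressionGMM(x).fit(K=3, n_inits=4, seed=9)
        np.testing.assert_array_equal(m1.posteriors, m2.posteriors)
        assert m1.loglik == m2.loglik

    def test_k_bounds(self):
        x, _ = self.blobs()
        with pytest.raises(ValueError):
            CoexpressionGMM(x).fit(K=0)
        with pytest.raises(ValueError):
            CoexpressionGMM(x).fit(K=len(x))

    def test_free_parameter_count(self):
        x, _ = self.blobs()
        model = CoexpressionGMM(x).fit(K=2, n_inits=1, seed=0)
        d = x.shape[1]
        assert model.n_free_parameters == (2 - 1) + 2 * d + 2 * d * (d + 1) // 2


class TestICL:
    def test_hard_posteriors_reduce_to_bic(self):
        x, _ = TestGMM.blobs(seed=5)
        model = CoexpressionGMM(x).fit(K=2, n_inits=3, seed=0)
        hard = np.zeros_like(model.posteriors)
        hard[np.arange(len(x)), model.hard_labels()] = 1.0
        model.posteriors = hard
        assert icl(model, len(x)) == pytest.approx(model.bic)

    def test_direct_formula(self):
        x, _ = TestGMM.blobs(seed=6)
        model = CoexpressionGMM(x).fit(K=2, n_inits=2, seed=0)
        tau = np.clip(model.posteriors, 1e-300, 1)
        ent = -np.sum(model.posteriors * np.log(tau))
        expected = (
            -2 * model.loglik + model.n_free_parameters * np.log(len(x)) + 2 * ent
        )
        assert icl(model, len(x)) == pytest.approx(expected)


class TestRelabel:
    def test_by_decreasing_size_with_ties(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        out = _relabel_by_size(labels, 3)
        # component 2 (size 3) -> 1; tie between 0 and 1 -> lowest index first
        np.testing.assert_array_equal(out, [2, 2, 3, 3, 1, 1, 1])


class TestSelectModel:
    def test_planted_single_cluster_selects_smallest_k(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(150, 4)) * 0.1
        res = select_model(x, grid=(5, 10, 15), loop1_inits=2, loop2_inits=3, seed=1,
                           interval_halfwidth=2)
        assert res.K == res.icl_loop2.index.min()
        assert res.convex
        assert np.all(np.diff(res.icl_loop2.to_numpy()) >= 0)

    def test_determinism_and_checkpoint_resume(self, tmp_path):
        cm, design, labels = simulate_coexpression(
            n_clusters=3, genes_per_cluster=60, seed=2
        )
        norm = tmm_factors(cm)
        profiles, c0 = expression_profiles(cm, norm, 50.0)
        data = arcsine_transform(profiles)
        kw = dict(grid=(2, 4, 6), loop1_inits=2, loop2_inits=4, seed=5,
                  interval_halfwidth=1, gene_ids=profiles.index.tolist(),
                  cluster0=c0)
        r1 = select_model(data, checkpoint_dir=tmp_path, **kw)
        assert any(tmp_path.iterdir())  # checkpoints written
        r2 = select_model(data, checkpoint_dir=tmp_path, **kw)  # resumes
        r3 = select_model(data, **kw)  # fresh, no checkpoints
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)
        pd.testing.assert_series_equal(r1.assignments, r3.assignments)
        assert r1.K == r3.K

    def test_assignment_partition(self):
        cm, design, labels = simulate_coexpression(
            n_clusters=3, genes_per_cluster=50, seed=3
        )
        norm = tmm_factors(cm)
        profiles, c0 = expression_profiles(cm, norm, 50.0)
        data = arcsine_transform(profiles)
        res = select_model(
            data, gene_ids=profiles.index.tolist(), cluster0=c0,
            grid=(2, 3, 4), loop1_inits=2, loop2_inits=3, seed=0,
            interval_halfwidth=1,
        )
        assert sorted(res.assignments.index) == sorted(cm.gene_ids)
        assert (res.assignments.loc[c0] == 0).all() if c0 else True
        clustered = res.assignments[res.assignments > 0]
        assert set(clustered.unique()) == set(range(1, res.K + 1))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            select_model(np.zeros((4, 2)), grid=(5, 10))
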