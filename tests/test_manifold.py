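"""PCA/t-SNE latent factors and manifold-dynamics analyses."""

import numpy as np
import pytest

from eegmanifold import (
    Embedding,
    bifurcation_projection,
    cluster_similarity,
    dims_for_variance,
    pca,
    smooth,
    trajectories,
    tsne,
)
from eegmanifold.manifold import path_length
from eegmanifold.tsne import conditional_probabilities, joint_probabilities, tsne_embed


def _brute_force_joint_p(X, sigmas):
    """Literal double-loop construction of the symmetrized joint P."""
    n = len(X)
    P_cond = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            P_cond[i, j] = np.exp(-np.sum((X[i] - X[j]) ** 2) / (2 * sigmas[i] ** 2))
        P_cond[i] /= P_cond[i].sum()
    return (P_cond + P_cond.T) / (2 * n)


class TestSmoothing:
    def test_zero_width_is_identity(self, rng):
        X = rng.standard_normal((30, 4))
        np.testing.assert_array_equal(smooth(X, 0), X)

    def test_impulse_becomes_gaussian_with_mass_preserved(self):
        X = np.zeros((101, 1))
        X[50] = 1.0
        out = smooth(X, 3.0)
        assert out.sum() == pytest.approx(1.0, rel=0.01)
        assert out[50] == out.max()
        # symmetric bell
        np.testing.assert_allclose(out[45:50], out[55:50:-1], rtol=1e-6)

    def test_constant_input_unchanged(self):
        X = np.full((40, 3), 2.5)
        np.testing.assert_allclose(smooth(X, 2.0), X, rtol=1e-9)

    def test_no_leakage_across_trials(self):
        X = np.zeros((40, 1))
        X[19] = 1.0  # last sample of trial 0
        trials = np.repeat([0, 1], 20)
        out = smooth(X, 2.0, trial_ids=trials)
        assert np.all(out[20:] == 0)

    def test_width_exceeding_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth(rng.standard_normal((10, 2)), 11.0)


class TestPCA:
    def test_exact_planar_data_fully_explained_by_two_components(self, rng):
        basis = rng.standard_normal((2, 10))
        coords = rng.standard_normal((200, 2))
        X = coords @ basis
        emb = pca(X, n_components=2)
        cum = emb.params["cumulative_explained_variance"]
        assert cum[1] == pytest.approx(1.0, abs=1e-8)
        assert dims_for_variance(emb, 0.8) == 2 or dims_for_variance(emb, 0.8) == 1

    def test_isotropic_gaussian_spreads_variance_evenly(self, rng):
        X = rng.standard_normal((10_000, 5))
        emb = pca(X, n_components=2)
        evr = emb.params["explained_variance_ratio"]
        np.testing.assert_allclose(evr, 0.2, atol=0.03)

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        """Eckart-Young: squared residual of the rank-k projection equals the
        sum of discarded covariance eigenvalues."""
        X = rng.standard_normal((300, 6)) @ rng.standard_normal((6, 6))
        k = 2
        emb = pca(X, n_components=k)
        comps = emb.params["components"]
        Xc = X - X.mean(axis=0)
        recon = emb.points @ comps
        resid = np.sum((Xc - recon) ** 2) / (len(X) - 1)
        eigvals = np.linalg.eigvalsh(np.cov(Xc.T))[::-1]
        assert resid == pytest.approx(eigvals[k:].sum(), rel=1e-8)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        X = rng.standard_normal((100, 7))
        emb = pca(X, n_components=3)
        sk = SkPCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            emb.params["explained_variance_ratio"][:3],
            sk.explained_variance_ratio_, rtol=1e-8)
        for ours, theirs in zip(emb.params["components"], sk.components_):
            assert min(np.abs(ours - theirs).max(),
                       np.abs(ours + theirs).max()) < 1e-8

    def test_constant_columns_do_not_produce_nans(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 2] = 7.0
        emb = pca(X, n_components=2)
        assert np.all(np.isfinite(emb.points))


class TestTsneProbabilities:
    def test_conditional_rows_sum_to_one_and_match_perplexity(self, rng):
        X = rng.standard_normal((40, 6))
        P, sigmas = conditional_probabilities(X, perplexity=12.0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        H = -np.sum(np.where(P > 0, P * np.log(np.maximum(P, 1e-300)), 0.0), axis=1)
        np.testing.assert_allclose(np.exp(H), 12.0, atol=1e-3)

    def test_joint_p_matches_brute_force_double_loop(self, rng):
        X = rng.standard_normal((20, 4))
        P, sigmas = joint_probabilities(X, perplexity=8.0)
        P_brute = _brute_force_joint_p(X, sigmas)
        np.testing.assert_allclose(P, P_brute, atol=1e-10)
        assert P.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_p_invariant_to_translation_and_rotation(self, rng):
        X = rng.standard_normal((25, 3))
        P0, _ = joint_probabilities(X, perplexity=10.0)
        P1, _ = joint_probabilities(X + 5.0, perplexity=10.0)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        P2, _ = joint_probabilities(X @ Q, perplexity=10.0)
        np.testing.assert_allclose(P0, P1, atol=1e-9)
        np.testing.assert_allclose(P0, P2, atol=1e-9)

    def test_infeasible_perplexity_rejected(self, rng):
        with pytest.raises(ValueError):
            conditional_probabilities(rng.standard_normal((10, 2)), perplexity=10.0)


class TestTsneEmbedding:
    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        X = np.vstack([rng.normal(c, 1.0, (50, 5)) for c in (0.0, 10.0, 20.0)])
        labels = np.repeat([0, 1, 2], 50)
        emb = tsne(X, perplexity=20, seed=0, n_iter=600, labels=labels)
        assert silhouette_score(emb.points, labels) >= 0.8

    def test_kl_decreases_and_settles(self, rng):
        """KL(P||Q) falls over the second half of the run and is
        non-increasing once the optimizer has settled (last quarter)."""
        X = np.vstack([rng.normal(c, 1.0, (30, 4)) for c in (0.0, 8.0)])
        _, diag = tsne_embed(X, perplexity=15, seed=1, n_iter=400)
        kl = diag["kl_trace"]
        assert kl[-1] <= kl[200]
        assert np.all(np.diff(kl[300:]) <= 1e-6)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((30, 4))
        Y1, _ = tsne_embed(X, perplexity=10, seed=3, n_iter=150)
        Y2, _ = tsne_embed(X, perplexity=10, seed=3, n_iter=150)
        np.testing.assert_array_equal(Y1, Y2)

    def test_duplicate_points_are_jittered_with_warning(self, rng):
        X = np.vstack([rng.standard_normal((10, 3))] * 2)  # every point doubled
        with pytest.warns(UserWarning, match="duplicate"):
            Y, _ = tsne_embed(X, perplexity=5, seed=0, n_iter=50)
        assert np.all(np.isfinite(Y))


class TestClusterSimilarity:
    def _emb(self, points, labels):
        return Embedding(points=np.asarray(points, float), method="tsne",
                         labels=np.asarray(labels))

    def test_identical_clusters_score_the_within_value(self, rng):
        pts = rng.standard_normal((20, 2))
        emb = self._emb(np.vstack([pts, pts]), ["a"] * 20 + ["b"] * 20)
        sim = cluster_similarity(emb).values
        assert sim.loc["a", "b"] == pytest.approx(sim.loc["a", "a"], abs=1e-9)

    def test_symmetry_and_distance_monotonicity(self, rng):
        a = rng.standard_normal((15, 2))
        b = rng.standard_normal((15, 2)) + [5, 0]
        far = b + [20, 0]
        near_sim = cluster_similarity(
            self._emb(np.vstack([a, b]), ["a"] * 15 + ["b"] * 15)).values
        far_sim = cluster_similarity(
            self._emb(np.vstack([a, far]), ["a"] * 15 + ["b"] * 15)).values
        assert near_sim.loc["a", "b"] == pytest.approx(near_sim.loc["b", "a"])
        assert far_sim.loc["a", "b"] < near_sim.loc["a", "b"]

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_similarity(self._emb(rng.standard_normal((5, 2)), ["x"] * 5))


class TestTrajectories:
    def _circle_embedding(self, n=50, trials=1):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        points = np.vstack([pts] * trials)
        return Embedding(
            points=points, method="tsne",
            labels=np.repeat(["c"], n * trials),
            trial_ids=np.repeat(np.arange(trials), n),
            time_ids=np.tile(np.arange(n), trials),
        )

    def test_ordered_circle_nearly_closes(self):
        traj = trajectories(self._circle_embedding())
        assert traj.closure[0] <= 0.05

    def test_single_trial_average_equals_trial_path(self):
        emb = self._circle_embedding()
        traj = trajectories(emb, resample_points=50)
        np.testing.assert_allclose(traj.mean_paths["c"], traj.paths[0], atol=1e-9)

    def test_time_shuffling_lengthens_smooth_paths(self, rng):
        emb = self._circle_embedding()
        ordered_len = path_length(trajectories(emb).paths[0])
        shuffled = Embedding(
            points=emb.points, method="tsne", labels=emb.labels,
            trial_ids=emb.trial_ids,
            time_ids=rng.permutation(emb.time_ids))
        shuffled_len = path_length(trajectories(shuffled).paths[0])
        assert shuffled_len > ordered_len

    def test_short_trials_excluded(self, rng):
        emb = Embedding(
            points=rng.standard_normal((5, 2)), method="tsne",
            labels=np.array(["a"] * 5),
            trial_ids=np.array([0, 0, 0, 1, 1]),
            time_ids=np.array([0, 1, 2, 0, 1]))
        traj = trajectories(emb)
        assert set(traj.paths) == {0}


class TestBifurcationProjection:
    def test_state_equal_to_reference(self, rng):
        ref_a = np.sin(np.linspace(0, 4 * np.pi, 50))
        ref_b = np.cos(np.linspace(0, 4 * np.pi, 50))  # orthogonal, zero-mean
        out = bifurcation_projection(ref_a, ref_a, ref_b)
        np.testing.assert_allclose(out[0], [1.0, 0.0], atol=1e-6)

    def test_state_orthogonal_to_both_references(self, rng):
        t = np.linspace(0, 4 * np.pi, 200)
        ref_a, ref_b = np.sin(t), np.cos(t)
        state = np.sin(2 * t)
        out = bifurcation_projection(state, ref_a, ref_b)
        np.testing.assert_allclose(out[0], [0.0, 0.0], atol=1e-6)

    def test_mixture_coordinate_monotone_in_lambda(self, rng):
        """For noisy mixtures lam*a + (1-lam)*b + noise, the first coordinate
        rises with lam (an exact noise-free mixture is degenerate: after
        controlling for b it correlates perfectly with a at any lam > 0)."""
        from scipy.stats import spearmanr

        ref_a = rng.standard_normal(80)
        ref_b = rng.standard_normal(80)
        lams = np.linspace(0.05, 0.95, 10)
        states = np.stack([
            l * ref_a + (1 - l) * ref_b + 0.5 * rng.standard_normal(80)
            for l in lams
        ])
        out = bifurcation_projection(states, ref_a, ref_b)
        rho = spearmanr(lams, out[:, 0]).statistic
        assert rho >= 0.9

    def test_matches_partial_correlation_oracle(self, rng):
        """Independent oracle: pingouin's partial correlation."""
        import pandas as pd
        import pingouin as pg

        x = rng.standard_normal(60)
        a = x + 0.5 * rng.standard_normal(60)
        b = rng.standard_normal(60)
        out = bifurcation_projection(x, a, b)
        df = pd.DataFrame({"x": x, "a": a, "b": b})
        expected = pg.partial_corr(df, x="x", y="a", covar="b")["r"].iloc[0]
        assert out[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_state_is_missing(self):
        out = bifurcation_projection(np.zeros(10), np.arange(10.0), np.ones(10))
        assert np.all(np.isnan(out[0]))
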