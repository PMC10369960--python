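"""Population analyses: normalization, condition-independent removal,
restretching, PCA, dPCA (marginalization identities and planted-structure
recovery), axis overlap, and CCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from interareal.population import (
    MARGINALS,
    StretchPolicy,
    axis_overlap,
    cca_similarity,
    condition_average,
    dpca,
    dpca_marginalize,
    normalize_units,
    pca,
    remove_condition_independent,
    restretch,
)
from interareal.synth import generate_session, preset


class TestNormalize:
    def test_constant_rate_square_rooted(self):
        x = np.full((1, 2, 2, 10), 4.0)
        out = normalize_units(x)
        np.testing.assert_allclose(out, 2.0)

    def test_zero_unit_unchanged(self):
        x = np.zeros((2, 3, 5))
        x[0] = 9.0
        out = normalize_units(x)
        np.testing.assert_allclose(out[0], 3.0)
        np.testing.assert_allclose(out[1], 0.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            normalize_units(np.array([[-1.0, 2.0]]))


class TestConditionIndependent:
    def test_condition_invariant_data_fully_removed(self):
        t = np.linspace(0, 1, 20)
        X = np.tile(t, (3, 2, 2, 1)) * np.arange(1, 4)[:, None, None, None]
        resid, ci, frac = remove_condition_independent(X)
        np.testing.assert_allclose(resid, 0, atol=1e-12)
        assert frac == pytest.approx(1.0)

    def test_residual_condition_means_vanish(self, rng):
        X = rng.normal(size=(4, 2, 2, 30))
        resid, _, _ = remove_condition_independent(X)
        np.testing.assert_allclose(resid.mean(axis=(1, 2)), 0, atol=1e-12)

    def test_planted_ci_fraction_recovered(self, rng):
        """Both synthetic presets plant ~80% condition-independent variance;
        the estimator recovers it within 2% absolute."""
        for name in ("dlpfc_like", "pmd_like"):
            sess, truth = generate_session(preset(name).with_(n_trials=300), rng)
            X = sess.rates.transpose(1, 0, 2)  # (unit, trial, time)
            _, _, frac = remove_condition_independent(X)
            assert abs(frac - truth.ci_fraction) < 0.02

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            remove_condition_independent(np.zeros((3, 1, 10)))


class TestRestretch:
    def _ramp_trials(self, B, n, T, dt=1.0):
        t = np.arange(T) * dt
        return np.tile(t, (B, n, 1))

    def test_median_timed_trial_is_identity(self):
        pol = StretchPolicy.dlpfc_style()
        T = 1600
        trials = self._ramp_trials(1, 2, T)
        target = np.array([150.0])
        cb = target + pol.median_tc
        move = cb + pol.median_rt
        out, kept = restretch(trials, target, cb, move, 1.0, pol)
        assert kept.tolist() == [0]
        grid = pol.canonical_times(1.0)
        np.testing.assert_allclose(out[0, 0], grid + 150.0, atol=1e-9)

    def test_linear_rates_stay_linear_and_mapping_monotone(self):
        pol = StretchPolicy.dlpfc_style()
        T = 2000
        trials = self._ramp_trials(3, 1, T)
        target = np.array([200.0, 150.0, 300.0])
        cb = target + np.array([500.0, 900.0, 735.0])
        move = cb + np.array([400.0, 700.0, 527.0])
        out, kept = restretch(trials, target, cb, move, 1.0, pol)
        assert kept.size == 3
        for i in range(3):
            d = np.diff(out[i, 0])
            assert np.all(d > 0)  # a monotone map of a ramp stays monotone
        # knots land exactly on the canonical events
        grid = pol.canonical_times(1.0)
        i_cb = int(np.argmin(np.abs(grid - pol.median_tc)))
        np.testing.assert_allclose(out[:, 0, i_cb], cb, atol=1.0)

    def test_too_short_trial_dropped(self):
        pol = StretchPolicy.dlpfc_style()
        trials = self._ramp_trials(2, 1, 1500)
        target = np.array([150.0, 150.0])
        cb = target + np.array([735.0, 735.0])
        move = cb + np.array([527.0, 2000.0])  # second trial runs off the end
        out, kept = restretch(trials, target, cb, move, 1.0, pol)
        assert kept.tolist() == [0]

    def test_pmd_style_concatenates_two_segments(self):
        pol = StretchPolicy.pmd_style()
        grid = pol.canonical_times(1.0)
        seg1 = np.arange(-100.0, 367.5, 1.0)
        assert grid.size == seg1.size + np.arange(-368.0, 465.5, 1.0).size


class TestPCA:
    def test_one_dimensional_data_fully_captured(self, rng):
        v = rng.normal(size=5)
        coef = rng.normal(size=40)
        X = np.outer(v, coef)
        res = pca(X, 3)
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert axis_overlap(res.axes[0], v / np.linalg.norm(v)) == pytest.approx(1.0)

    def test_components_capped_at_rank(self, rng):
        X = rng.normal(size=(3, 10))
        res = pca(X, 8)
        assert res.axes.shape[0] == 3


class TestDPCA:
    def _tensor(self, rng, n=6):
        return rng.normal(size=(n, 2, 2, 15))

    def test_marginalization_completeness_exact(self, rng):
        X = self._tensor(rng)
        parts = dpca_marginalize(X)
        Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
        total = sum(parts[m] for m in MARGINALS)
        np.testing.assert_allclose(total, Xc, atol=1e-12)

    def test_encoder_orthonormal_and_variances_bounded(self, rng):
        X = self._tensor(rng, n=8)
        axes = dpca(X, k_per_marginal=3)
        s = 0.0
        for ax in axes.values():
            P = ax.encoder
            np.testing.assert_allclose(P.T @ P, np.eye(P.shape[1]), atol=1e-8)
            s += ax.variance_captured.sum()
        assert s <= 1.0 + 1e-8

    def test_planted_axis_recovery_across_seeds(self):
        """A planted coding axis is recovered with |cos| > 0.9 at default
        SNR, across 20 session seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sess, truth = generate_session(
                preset("dlpfc_like").with_(n_trials=250, seed=seed), rng)
            X = condition_average(sess.rates,
                                  sess.labels["color"].to_numpy(),
                                  sess.labels["direction"].to_numpy())
            axes = dpca(X)
            cos = abs(np.dot(axes["direction"].axis, truth.axes["direction"]))
            assert cos > 0.9

    def test_direction_only_session_has_no_color_variance(self, rng):
        sess, truth = generate_session(preset("pmd_like").with_(n_trials=400), rng)
        X = condition_average(sess.rates,
                              sess.labels["color"].to_numpy(),
                              sess.labels["direction"].to_numpy())
        axes = dpca(X)
        assert axes["direction"].variance_captured[0] > 0.01
        assert axes["color"].variance_captured[0] < 0.005
        assert axes["target_config"].variance_captured[0] < 0.005

    def test_full_rank_solution_matches_least_squares_oracle(self, rng):
        # with k = n and vanishing ridge, P D X equals the unconstrained
        # least-squares prediction of the marginal from X (computed
        # independently with lstsq)
        X = self._tensor(rng, n=4)
        axes = dpca(X, k_per_marginal=4, regularization=1e-12)
        parts = dpca_marginalize(X)
        Xf = (X - X.mean(axis=(1, 2, 3), keepdims=True)).reshape(4, -1)
        for m in MARGINALS:
            rec = axes[m].encoder @ (axes[m].decoder @ Xf)
            coef, *_ = np.linalg.lstsq(Xf.T, parts[m].reshape(4, -1).T, rcond=None)
            np.testing.assert_allclose(rec, coef.T @ Xf, atol=1e-5)


class TestAxisOverlap:
    def test_identical_and_orthogonal(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        assert axis_overlap(a, a) == pytest.approx(1.0)
        assert axis_overlap(a, b) == 0.0
        assert axis_overlap(a, -a) == pytest.approx(1.0)  # sign-invariant

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            axis_overlap(np.zeros(3), np.ones(3))

    @given(arrays(np.float64, 5, elements=st.floats(-5, 5)),
           arrays(np.float64, 5, elements=st.floats(-5, 5)))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_in_unit_interval(self, a, b):
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        assert 0.0 <= axis_overlap(a, b) <= 1.0 + 1e-12


class TestCCA:
    def test_self_similarity_is_one(self, rng):
        X = rng.normal(size=(6, 120))
        assert cca_similarity(X, X.copy(), 4, 4) == pytest.approx(1.0, abs=1e-6)

    def test_permuted_time_bins_near_permutation_null(self, rng):
        """Destroying temporal correspondence drops the mean canonical
        correlation to its empirical permutation-null level."""
        X = rng.normal(size=(6, 400))
        Y = X[:, rng.permutation(400)]
        observed = cca_similarity(X, Y, 4, 4)
        null = [
            cca_similarity(X, X[:, rng.permutation(400)], 4, 4)
            for _ in range(10)
        ]
        hi = np.mean(null) + 4 * np.std(null)
        assert observed < max(hi, 0.5)

    def test_mismatched_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cca_similarity(rng.normal(size=(4, 50)), rng.normal(size=(4, 60)))
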