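"""Multi-area network construction and simulation: connectivity masks,
Dale's law, the Euler update (against hand-computed and closed-form
oracles), decision readout, and behavior aggregation."""

import numpy as np
import pytest

from interareal.network import (
    ArchitectureConfig,
    behavior_curves,
    build_connectivity,
    decide,
    load_params,
    save_params,
    simulate,
)
from interareal.task import generate_batch, sample_conditions


class TestConnectivity:
    def test_exemplar_layout_300_units(self, rng):
        arch = ArchitectureConfig(n_units=300, n_areas=3)
        p = build_connectivity(arch, rng)
        assert arch.units_per_area == 100
        for k in range(3):
            assert arch.exc_indices(k).size == 80
            assert arch.inh_indices(k).size == 20
            assert np.all(p.sign_vector[arch.exc_indices(k)] == 1)
            assert np.all(p.sign_vector[arch.inh_indices(k)] == -1)

    def test_interareal_blocks_only_between_adjacent_areas(self, rng):
        arch = ArchitectureConfig(n_units=300, n_areas=3)
        p = build_connectivity(arch, rng)
        m = p.connectivity_mask
        # no direct area1 <-> area3 connections
        s1, s3 = arch.area_slice(0), arch.area_slice(2)
        assert not m[s3, s1].any() and not m[s1, s3].any()
        # feedforward E->E density near its Bernoulli parameter
        ff = m[np.ix_(arch.exc_indices(1), arch.exc_indices(0))]
        assert abs(ff.mean() - 0.10) < 4 * np.sqrt(0.1 * 0.9 / ff.size)
        fb = m[np.ix_(arch.exc_indices(0), arch.exc_indices(1))]
        assert abs(fb.mean() - 0.05) < 4 * np.sqrt(0.05 * 0.95 / fb.size)
        # no long-range inhibition, no feedforward E->I by default
        assert not m[np.ix_(arch.inh_indices(1), arch.exc_indices(0))].any()
        assert not m[np.ix_(arch.exc_indices(1), arch.inh_indices(0))].any()

    def test_zero_interareal_density_gives_block_diagonal(self, rng):
        arch = ArchitectureConfig(n_units=30, n_areas=3,
                                  ff_ee_density=0.0, fb_ee_density=0.0)
        p = build_connectivity(arch, rng)
        m = p.connectivity_mask
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert not m[arch.area_slice(i), arch.area_slice(j)].any()

    def test_dale_sign_consistency_exhaustive(self, rng):
        arch = ArchitectureConfig(n_units=60, n_areas=3)
        p = build_connectivity(arch, rng)
        for j in range(60):
            col = p.W_rec[:, j]
            nz = col[col != 0]
            if nz.size:
                assert np.all(np.sign(nz) == p.sign_vector[j])
        # readout taps only the last area's excitatory units, nonnegatively
        read_cols = np.nonzero(p.out_mask[0])[0]
        np.testing.assert_array_equal(read_cols, arch.exc_indices(2))
        assert np.all(p.W_out >= 0)

    def test_indivisible_units_rejected(self, rng):
        with pytest.raises(ValueError):
            ArchitectureConfig(n_units=100, n_areas=3)

    def test_checkpoint_roundtrip(self, tiny_params, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_params(path, tiny_params, seed=3)
        loaded = load_params(path)
        np.testing.assert_array_equal(loaded.W_rec, tiny_params.W_rec)
        np.testing.assert_array_equal(loaded.connectivity_mask,
                                      tiny_params.connectivity_mask)
        assert loaded.arch == tiny_params.arch


class TestSimulate:
    def test_closed_form_decay_with_zero_weights(self, short_task, rng):
        arch = ArchitectureConfig(n_units=6, n_areas=3, rec_noise_sd=0.0)
        p = build_connectivity(arch, rng)
        p.W_in[:] = 0; p.W_rec[:] = 0; p.W_out[:] = 0; p.b_rec[:] = 0
        batch = generate_batch(sample_conditions(1, short_task, rng)[:2],
                               short_task, rng)
        c = np.linspace(0.5, 2.0, 6)
        res = simulate(p, batch, None, 0.0, store="x", x0=c)
        alpha = arch.alpha
        for t in range(batch.n_steps):
            np.testing.assert_allclose(res.x[0, t], (1 - alpha) ** t * c,
                                       rtol=1e-10, atol=1e-12)

    def test_single_euler_step_matches_hand_computation(self):
        # 2-unit network, one area, all quantities chosen by hand:
        # alpha = dt/tau = 0.2, x0 = [1, -1], r0 = [1, 0]
        # x1 = 0.8*x0 + 0.2*(W r0 + W_in u0 + b)
        arch = ArchitectureConfig(n_units=2, n_areas=1, exc_fraction=0.5,
                                  dale=False, tau=50.0, dt=10.0,
                                  rec_noise_sd=0.0,
                                  readout_last_area_only=False,
                                  input_first_area_only=False)
        p = build_connectivity(arch, np.random.default_rng(0))
        p.connectivity_mask[:] = True
        p.W_rec = np.array([[0.5, -0.3], [0.2, 0.1]])
        p.W_in = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        p.b_rec = np.array([0.1, -0.2])
        p.W_out = np.zeros((2, 2))
        from interareal.task import TrialBatch
        u = np.zeros((1, 2, 4)); u[0, 0, :2] = [2.0, 3.0]
        batch = TrialBatch(u, np.zeros((1, 2, 2)), np.ones((1, 2), bool),
                           np.array([[0, 0, 0, 2, 2]]), [None], dt=10.0)
        res = simulate(p, batch, None, 0.0, store="x", x0=np.array([1.0, -1.0]))
        # hand computation: W r0 = [0.5, 0.2]; W_in u0 = [2, 3]
        # x1 = 0.8*[1,-1] + 0.2*([0.5,0.2]+[2,3]+[0.1,-0.2]) = [1.32, -0.2]
        np.testing.assert_allclose(res.x[0, 1], [1.32, -0.2], atol=1e-12)

    def test_rates_nonnegative_and_deterministic_without_noise(
        self, tiny_params, short_task, rng
    ):
        batch = generate_batch(sample_conditions(1, short_task, rng)[:4],
                               short_task, rng)
        r1 = simulate(tiny_params, batch, None, 0.0, store="r").r
        r2 = simulate(tiny_params, batch, None, 0.0, store="r").r
        assert np.all(r1 >= 0)
        np.testing.assert_array_equal(r1, r2)

    def test_linear_scaling_in_positive_regime(self, short_task, rng):
        # all-positive weights, positive initial state, no bias/noise:
        # relu is identity, so currents scale linearly with the input gain
        arch = ArchitectureConfig(n_units=6, n_areas=1, dale=False,
                                  rec_noise_sd=0.0, spectral_radius=0.5,
                                  readout_last_area_only=False,
                                  input_first_area_only=False)
        p = build_connectivity(arch, rng)
        p.W_rec = np.abs(p.W_rec) * 0.05
        p.W_in = np.abs(p.W_in)
        p.b_rec[:] = 0
        cfg = short_task.with_(input_noise_sd=0.0)
        conds = [c for c in sample_conditions(1, cfg, rng) if c.signed_coherence > 0]
        batch = generate_batch(conds[:2], cfg, rng)
        x0 = np.full(6, 0.1)
        res1 = simulate(p, batch, None, 0.0, store="x", x0=x0)
        batch.inputs *= 3.0
        res3 = simulate(p, batch, None, 0.0, store="x", x0=3 * x0)
        np.testing.assert_allclose(res3.x, 3 * res1.x, rtol=1e-8, atol=1e-10)


class TestDecide:
    def _z(self, T=100):
        return np.zeros((1, T, 2))

    def test_threshold_crossing_sets_choice_and_rt(self):
        z = self._z()
        z[0, 62:, 1] = 0.7  # right DV crosses at step 62; onset step 0
        choice, rt, crit = decide(z, 0.6, np.array([0]), np.array([100]), 10.0)
        assert choice[0] == 1 and rt[0] == 620.0 and crit[0] == "threshold"

    def test_endpoint_fallback_when_no_crossing(self):
        z = self._z()
        z[0, :, 0] = 0.55
        z[0, :, 1] = 0.40
        choice, rt, crit = decide(z, 0.6, np.array([0]), np.array([100]), 10.0)
        assert choice[0] == 0 and np.isnan(rt[0]) and crit[0] == "endpoint"

    def test_simultaneous_crossing_tiebreak(self):
        z = self._z()
        z[0, 30:, 0] = 0.65
        z[0, 30:, 1] = 0.70  # both cross at step 30, right is larger
        choice, _, _ = decide(z, 0.6, np.array([0]), np.array([100]), 10.0)
        assert choice[0] == 1
        z[0, 30:, 1] = 0.65  # exact tie -> left
        choice, _, _ = decide(z, 0.6, np.array([0]), np.array([100]), 10.0)
        assert choice[0] == 0

    def test_crossing_before_onset_ignored(self):
        z = self._z()
        z[0, 5:20, 0] = 0.9  # early transient before checkerboard onset
        choice, rt, crit = decide(z, 0.6, np.array([40]), np.array([100]), 10.0)
        assert crit[0] == "endpoint"

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            decide(self._z(), 1.5, np.array([0]), np.array([100]), 10.0)


class TestBehavior:
    def test_zero_network_all_endpoint_decisions(self, short_task, rng):
        arch = ArchitectureConfig(n_units=6, n_areas=3, rec_noise_sd=0.0)
        p = build_connectivity(arch, rng)
        p.W_in[:] = 0; p.W_rec[:] = 0; p.W_out[:] = 0
        df = behavior_curves(p, short_task, 2, rng, rec_noise_sd=0.0)
        assert df.attrs["endpoint_fraction"] == 1.0
        assert df["mean_rt"].isna().all()
        assert len(df) == 14
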