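"""Decoding and usable information: the variational bound and its clipping,
the MLP decoder against chance and Bayes oracles, the data-processing
inequality on a synthetic Markov chain, and SVM session decoding with
shuffle significance."""

import numpy as np
import pytest

from interareal.info import (
    DecodeDataset,
    binary_entropy,
    decode_variable,
    shuffle_significance,
    svm_session_decode,
    usable_information,
)
from interareal.synth import calibrate_axis_variance, generate_session, preset


class TestUsableInformation:
    @pytest.mark.parametrize("lce, hy, expected",
                             [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0),
                              (1.2, 1.0, 0.0), (0.3, 1.0, 0.7)])
    def test_bound_and_clipping(self, lce, hy, expected):
        assert usable_information(lce, hy) == pytest.approx(expected)

    def test_negative_cross_entropy_rejected(self):
        with pytest.raises(ValueError):
            usable_information(-0.1)

    def test_never_exceeds_label_entropy(self, rng):
        for _ in range(200):
            lce = rng.uniform(0, 3)
            p = rng.uniform(0.01, 0.99)
            h = binary_entropy(p)
            assert 0.0 <= usable_information(lce, h) <= h


def _dataset_from_arrays(X, y, n_train, rng):
    perm = rng.permutation(len(y))
    return DecodeDataset(
        features=X, labels={"v": y},
        train_idx=perm[:n_train], test_idx=perm[n_train:],
    )


class TestMLPDecoder:
    def test_separable_data_reaches_low_cross_entropy(self, rng):
        n = 600
        y = rng.integers(2, size=n)
        X = rng.normal(size=(n, 8)) * 0.1
        X[:, 0] += 3.0 * (2 * y - 1)
        ds = _dataset_from_arrays(X, y, 400, rng)
        rep = decode_variable(ds, "v", rng, epochs=60)
        assert rep.accuracy > 0.99
        assert rep.cross_entropy_bits < 0.1
        assert rep.usable_bits > 0.9

    def test_uninformative_features_stay_at_chance(self, rng):
        n = 800
        y = rng.integers(2, size=n)
        X = rng.normal(size=(n, 8))
        ds = _dataset_from_arrays(X, y, 500, rng)
        rep = decode_variable(ds, "v", rng, epochs=40)
        assert abs(rep.accuracy - 0.5) < 0.08
        assert rep.usable_bits < 0.05

    def test_linear_variant_on_linear_problem(self, rng):
        n = 600
        y = rng.integers(2, size=n)
        X = rng.normal(size=(n, 5))
        X[:, 1] += 1.5 * (2 * y - 1)
        ds = _dataset_from_arrays(X, y, 400, rng)
        _rep = decode_variable(ds, "v", rng, variant="linear", epochs=60)
        assert _rep.accuracy > 0.85

    def test_decoder_tracks_bayes_accuracy(self):
        """On a calibrated Gaussian session with orthogonal planted axes the
        decoder reaches the closed-form Bayes accuracy within 3% absolute."""
        rng = np.random.default_rng(7)
        # direction is the only planted variable, so the Bayes accuracy is
        # the Phi closed form (no cross-channel route to the label)
        base = preset("pmd_like").with_(n_trials=2500)
        cfg = calibrate_axis_variance(base, "direction", 0.85,
                                      np.random.default_rng(11))
        sess, truth = generate_session(cfg, rng)
        from interareal.info import session_features
        X = session_features(sess)
        y = sess.labels["direction"].to_numpy()
        ds = _dataset_from_arrays(X, y, 1800, rng)
        rep = decode_variable(ds, "v", rng, epochs=80)
        assert 0.7 < truth.bayes_accuracy["direction"] < 0.95  # regime check
        assert abs(rep.accuracy - truth.bayes_accuracy["direction"]) < 0.03

    def test_usable_info_tracks_analytic_channel_information(self):
        """Usable information lands within 0.07 bits of the exact mutual
        information of the binary Gaussian channel (quadrature oracle) and
        respects it as a lower bound (up to estimator tolerance).  It also
        exceeds the coarser hard-decision value 1 - H_b(bayes accuracy),
        which discards the decoder's soft posterior."""
        rng = np.random.default_rng(3)
        base = preset("pmd_like").with_(n_trials=2500)
        cfg = calibrate_axis_variance(base, "direction", 0.9,
                                      np.random.default_rng(5))
        sess, truth = generate_session(cfg, rng)
        from interareal.info import session_features
        X = session_features(sess)
        y = sess.labels["direction"].to_numpy()
        ds = _dataset_from_arrays(X, y, 1800, rng)
        rep = decode_variable(ds, "v", rng, epochs=80)
        exact = truth.channel_information["direction"]
        assert exact is not None
        assert abs(rep.usable_bits - exact) < 0.07
        assert rep.usable_bits <= exact + 0.02
        hard = 1.0 - binary_entropy(truth.bayes_accuracy["direction"])
        assert rep.usable_bits >= hard - 0.02

    def test_non_binary_labels_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(3, size=50)
        ds = _dataset_from_arrays(X, y, 30, rng)
        with pytest.raises(ValueError):
            decode_variable(ds, "v", rng, epochs=2)


class TestDataProcessing:
    def test_information_cannot_grow_along_a_chain(self):
        """X -> Z1 -> Z2 with Z2 a noisy function of Z1: estimated usable
        information about X from Z2 never exceeds that from Z1 by more than
        the estimator tolerance (0.05 bits), over 20 seeds."""
        excess = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 700
            y = rng.integers(2, size=n)
            z1 = np.outer(2 * y - 1, np.ones(4)) + rng.normal(0, 1.2, size=(n, 4))
            z2 = z1 @ rng.normal(size=(4, 4)) / 2 + rng.normal(0, 1.5, size=(n, 4))
            ds1 = _dataset_from_arrays(z1, y, 450, rng)
            ds2 = _dataset_from_arrays(z2, y, 450, rng)
            i1 = decode_variable(ds1, "v", rng, epochs=40).usable_bits
            i2 = decode_variable(ds2, "v", rng, epochs=40).usable_bits
            excess.append(i2 - i1)
        assert max(excess) <= 0.05


class TestSessionDecoding:
    def test_direction_only_session_decodes_direction_only(self, rng):
        sess, _ = generate_session(preset("pmd_like").with_(n_trials=300), rng)
        acc_dir = svm_session_decode(sess, "direction", rng)
        acc_col = svm_session_decode(sess, "color", rng)
        acc_cfg = svm_session_decode(sess, "target_config", rng)
        assert acc_dir > 0.8
        assert abs(acc_col - 0.5) < 0.15
        assert abs(acc_cfg - 0.5) < 0.15

    def test_duplicated_units_leave_accuracy_essentially_unchanged(self, rng):
        sess, _ = generate_session(preset("dlpfc_like").with_(n_trials=250), rng)
        acc = svm_session_decode(sess, "direction", np.random.default_rng(0))
        import copy
        dup = copy.copy(sess)
        dup.rates = np.concatenate([sess.rates, sess.rates], axis=1)
        acc_dup = svm_session_decode(dup, "direction", np.random.default_rng(0))
        assert abs(acc - acc_dup) < 0.05

    def test_single_class_session_rejected(self, rng):
        sess, _ = generate_session(preset("pmd_like").with_(n_trials=60), rng)
        sess.labels["direction"] = 1
        with pytest.raises(ValueError):
            svm_session_decode(sess, "direction", rng)

    def test_shuffle_null_size_and_informative_flag(self, rng):
        sess, _ = generate_session(preset("pmd_like").with_(n_trials=200), rng)
        res = shuffle_significance(sess, "direction", rng, n_shuffles=100)
        assert res["null"].size == 100
        assert res["significant"] is True

    def test_shuffled_labels_fall_inside_null(self, rng):
        sess, _ = generate_session(preset("pmd_like").with_(n_trials=200), rng)
        sess.labels["direction"] = rng.permutation(
            sess.labels["direction"].to_numpy())
        res = shuffle_significance(sess, "direction", rng, n_shuffles=60)
        assert res["true_accuracy"] <= res["threshold"] + 0.1

    def test_type_one_error_calibration(self):
        """On label-free (pure noise) sessions the shuffle test fires at
        roughly its nominal 1% rate (binomial check over 150 sessions)."""
        hits = 0
        n_sessions = 150
        for seed in range(n_sessions):
            rng = np.random.default_rng(10_000 + seed)
            cfg = preset("pmd_like").with_(
                n_trials=120, n_units=8,
                axis_variance={"direction": 0.0, "color": 0.0,
                               "target_config": 0.0})
            sess, _ = generate_session(cfg, rng)
            res = shuffle_significance(sess, "direction", rng, n_shuffles=100)
            hits += res["significant"]
        from scipy import stats
        # accept if consistent with a true rate of 1% (two-sided, alpha 1e-3)
        p = stats.binomtest(hits, n_sessions, 0.01).pvalue
        assert p > 1e-3
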