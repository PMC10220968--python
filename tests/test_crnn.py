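"""Architecture, parameter-count, gradient and training tests for the CRNN."""

import numpy as np
import pytest

import ecgident as eid
from ecgident.crnn import CRNN, CRNNConfig, TrainSpec, count_parameters


class TestCountParameters:
    def test_per_layer_counts_seq94(self):
        table = count_parameters(CRNNConfig(seq_len=94, n_classes=48))
        assert table.counts() == [66_560, 49_408, 6_176, 10_304, 16_416, 385_280, 32_896, 6_192]

    @pytest.mark.parametrize(
        "seq_len,n_classes,total",
        [(94, 48, 573_232), (94, 18, 569_362), (94, 156, 587_164), (94, 90, 578_650),
         (188, 156, 972_188)],
    )
    def test_totals(self, seq_len, n_classes, total):
        assert count_parameters(CRNNConfig(seq_len=seq_len, n_classes=n_classes)).total == total

    def test_degenerate_single_class_head(self):
        t48 = count_parameters(CRNNConfig(seq_len=94, n_classes=48))
        t1 = count_parameters(CRNNConfig(seq_len=94, n_classes=1))
        assert t1.counts()[-1] == 129
        assert t1.counts()[:-1] == t48.counts()[:-1]

    def test_total_affine_in_classes_slope_129(self):
        totals = [count_parameters(CRNNConfig(seq_len=94, n_classes=n)).total for n in range(2, 201)]
        diffs = np.diff(totals)
        assert np.all(diffs == 129)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_flatten_growth_with_consecutive_beats(self, k):
        # dense-1 input grows as 32*ceil(94k/2); all other layers are k-independent
        cfg = CRNNConfig(seq_len=94 * k, n_classes=156)
        assert cfg.flatten_len == 32 * ((94 * k + 1) // 2)
        base = count_parameters(CRNNConfig(seq_len=94, n_classes=156)).total
        expected = base + (cfg.flatten_len - 1504) * 256
        assert count_parameters(cfg).total == expected

    def test_realized_network_matches_analytic_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cfg = CRNNConfig(
                seq_len=int(rng.integers(10, 200)), n_classes=int(rng.integers(2, 200)), seed=1
            )
            net = eid.build_crnn(cfg)
            assert net.parameter_counts() == count_parameters(cfg).counts()

    def test_table_totals_consistent(self):
        table = count_parameters(CRNNConfig(seq_len=94, n_classes=18))
        assert table.total == sum(r[2] for r in table.rows)


class TestBuildAndForward:
    def test_softmax_rows_sum_to_one_on_zeros(self):
        net = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=7, seed=2))
        probs = net.predict_proba(np.zeros((5, 94)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_same_seed_identical_initial_outputs(self):
        x = np.random.default_rng(3).normal(size=(4, 94))
        a = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=5, seed=9)).predict_proba(x)
        b = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=5, seed=9)).predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_seq_len_below_pool_size_rejected(self):
        with pytest.raises(eid.InvalidConfigError):
            CRNNConfig(seq_len=4, n_classes=3)

    def test_wrong_beat_length_rejected(self):
        net = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=3))
        with pytest.raises(eid.InvalidInputError):
            net.predict_proba(np.zeros((2, 188)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = CRNNConfig(
            seq_len=12, n_classes=3, lstm_units=(5, 4), conv_specs=((4, 3), (5, 5), (4, 8)),
            dense_units=(8, 6), dropout_rates=(0.0, 0.0), seed=3,
        )
        net = CRNN(cfg, dtype=np.float64)
        rng = np.random.default_rng(0)
        X = net._check_input(rng.normal(size=(4, 12)))
        onehot = np.zeros((4, 3))
        onehot[np.arange(4), [0, 1, 2, 1]] = 1.0

        def loss():
            p = net._forward(X, train=False)
            return float(-(onehot * np.log(p + 1e-12)).sum() / 4)

        probs = net._forward(X, train=True, rng=rng)
        grads = net._backward((probs - onehot) / 4)
        pick = np.random.default_rng(5)
        for key, p in net.parameters().items():
            for flat in pick.choice(p.size, size=min(3, p.size), replace=False):
                ix = np.unravel_index(flat, p.shape)
                eps, old = 1e-6, p[ix]
                p[ix] = old + eps
                lp = loss()
                p[ix] = old - eps
                lm = loss()
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(num) + abs(grads[key][ix]))
                assert abs(num - grads[key][ix]) / denom < 1e-4, key


class TestTraining:
    def test_loss_decreases_and_fits_benchmark(self, trained_net, split):
        net, history = trained_net
        train, _test, y_train, _y_test, _classes = split
        assert history["loss"][-1] < history["loss"][0]
        # non-increasing up to tolerance: no late-epoch blow-up
        assert min(history["loss"][-10:]) <= min(history["loss"][:10])
        assert history["accuracy"][-1] >= 0.95
        assert float((net.predict(train.beats) == y_train).mean()) >= 0.95

    def test_single_class_rejected(self):
        net = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=2, seed=0))
        with pytest.raises(eid.InvalidInputError):
            net.fit(np.zeros((4, 94)), np.zeros(4, dtype=int), TrainSpec(epochs=1))

    def test_label_row_mismatch_rejected(self):
        net = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=2, seed=0))
        with pytest.raises(eid.InvalidInputError):
            net.fit(np.zeros((4, 94)), np.array([0, 1]), TrainSpec(epochs=1))

    def test_fixed_seed_training_reproducible(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 94))
        y = np.repeat([0, 1, 2], 8)
        spec = TrainSpec(epochs=2, seed=4)
        nets = []
        for _ in range(2):
            net = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=3, seed=4))
            net.fit(X, y, spec)
            nets.append(net)
        np.testing.assert_array_equal(nets[0].predict_proba(X), nets[1].predict_proba(X))


class TestDeepFeatures:
    def test_shape_nonnegativity_determinism(self, trained_net, split):
        net, _history = trained_net
        train = split[0]
        feats = eid.extract_deep_features(net, train.beats[:10])
        assert feats.shape == (10, 128)
        assert np.all(feats >= 0)
        np.testing.assert_array_equal(feats, eid.extract_deep_features(net, train.beats[:10]))

    def test_softmax_of_features_reproduces_probabilities(self, trained_net, split):
        net, _history = trained_net
        train = split[0]
        feats = eid.extract_deep_features(net, train.beats[:8])
        W, b = net.output_layer()
        # replay the final layer at the network's own precision
        logits = (feats.astype(net.dtype) @ W.astype(net.dtype) + b.astype(net.dtype)).astype(float)
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs, net.predict_proba(train.beats[:8]), atol=1e-6)

    def test_untrained_network_rejected(self):
        net = eid.build_crnn(CRNNConfig(seq_len=94, n_classes=3))
        with pytest.raises(eid.InvalidStateError):
            eid.extract_deep_features(net, np.zeros((2, 94)))

    def test_wrong_length_rejected(self, trained_net):
        net, _history = trained_net
        with pytest.raises(eid.InvalidInputError):
            eid.extract_deep_features(net, np.zeros((2, 50)))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        cfg = CRNNConfig(seq_len=94, n_classes=4, seed=6)
        net = eid.build_crnn(cfg)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 94))
        net.fit(X, np.repeat([0, 1, 2, 3], 4), TrainSpec(epochs=1, seed=1))
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = CRNN.load(path)
        np.testing.assert_array_equal(net.predict_proba(X), loaded.predict_proba(X))
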