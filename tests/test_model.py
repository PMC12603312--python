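"""Network mechanics: normalization, downsampling, layer gradients, training smoke."""

import numpy as np
import pytest

from motifcaller.model import (
    CallerConfig,
    MotifCallerModel,
    TokenAlphabet,
    ctc_loss,
    forward,
    normalize_signal,
    train,
)
from motifcaller.nn import BiGRU, Conv1d, Linear, MaxPool1d


@pytest.fixture(scope="module")
def tiny_alphabet():
    return TokenAlphabet(tokens=("M0", "M1", "B0"))


@pytest.fixture(scope="module")
def tiny_model(tiny_alphabet):
    cfg = CallerConfig(
        conv_filters=(4, 4, 8, 8), rnn_layers=1, hidden=8, fc_size=16,
        n_classes=tiny_alphabet.n_classes, seed=0,
    )
    return MotifCallerModel(cfg, tiny_alphabet)


class TestNormalizeSignal:
    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_signal(np.full(50, 3.7)), np.zeros(50))

    def test_affine_invariance(self, rng):
        x = rng.normal(size=200)
        a = normalize_signal(x)
        b = normalize_signal(4.2 * x - 17.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_median_zero_mad_one(self, rng):
        x = rng.normal(5.0, 3.0, size=100_000)
        y = normalize_signal(x)
        assert abs(np.median(y)) < 0.01
        assert abs(np.median(np.abs(y - np.median(y))) - 1.0) < 0.01


class TestForwardPass:
    def test_downsampling_factor_is_64(self, tiny_model):
        for T in (64, 640, 6400):
            post = forward(tiny_model, np.random.default_rng(0).normal(size=T))
            assert post.T_frames == T // 64
        assert forward(tiny_model, np.random.default_rng(0).normal(size=6400)).T_frames == 100

    def test_rows_are_distributions(self, tiny_model, rng):
        post = forward(tiny_model, rng.normal(size=1280))
        np.testing.assert_allclose(np.exp(post.log_probs).sum(axis=1), 1.0, atol=1e-6)

    def test_too_short_read_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="too short"):
            forward(tiny_model, np.zeros(32))

    def test_ctc_loss_wrapper_uses_alphabet(self, tiny_model, rng):
        post = forward(tiny_model, rng.normal(size=640))
        loss = ctc_loss(post, ["M0", "M1"])
        assert np.isfinite(loss) and loss > 0
        with pytest.raises(KeyError):
            ctc_loss(post, ["M9"])


class TestLayerGradients:
    """Analytic backprop vs central finite differences on tiny layers."""

    @staticmethod
    def _check(layer, x, lengths, eps=1e-3, tol=2e-2):
        rng = np.random.default_rng(0)
        y = layer.forward(x, lengths)
        dy = rng.normal(size=y.shape).astype(np.float32)
        layer.zero_grad()
        dx = layer.backward(dy)
        loss = lambda out: float((out * dy).sum())
        # input gradient
        for idx in [(0, 1, 0), (0, 3, 0)]:
            up, dn = x.copy(), x.copy()
            up[idx] += eps
            dn[idx] -= eps
            num = (loss(layer.forward(up, lengths)) - loss(layer.forward(dn, lengths))) / (2 * eps)
            assert dx[idx] == pytest.approx(num, abs=tol, rel=tol)
        # parameter gradients
        layer.forward(x, lengths)
        layer.zero_grad()
        layer.backward(dy)
        for name, p in layer.params.items():
            flat = p.reshape(-1)
            g = layer.grads[name].reshape(-1)
            for j in (0, len(flat) // 2):
                orig = flat[j]
                flat[j] = orig + eps
                up_l = loss(layer.forward(x, lengths))
                flat[j] = orig - eps
                dn_l = loss(layer.forward(x, lengths))
                flat[j] = orig
                assert g[j] == pytest.approx((up_l - dn_l) / (2 * eps), abs=tol, rel=tol)

    def test_conv1d(self, rng):
        layer = Conv1d(2, 3, kernel=3, stride=2, rng=rng)
        x = rng.normal(size=(2, 8, 2)).astype(np.float32)
        self._check(layer, x, np.array([8, 6]))

    def test_maxpool(self, rng):
        layer = MaxPool1d(4)
        x = rng.normal(size=(2, 8, 3)).astype(np.float32)
        self._check(layer, x, np.array([8, 8]))

    def test_bigru_with_mask(self, rng):
        layer = BiGRU(3, 4, rng=rng)
        x = rng.normal(size=(2, 6, 3)).astype(np.float32)
        self._check(layer, x, np.array([6, 4]))

    def test_linear(self, rng):
        layer = Linear(3, 5, relu=True, rng=rng)
        x = rng.normal(size=(2, 4, 3)).astype(np.float32)
        self._check(layer, x, np.array([4, 4]))

    def test_gru_mask_blocks_padding_influence(self, rng):
        """Changing padded frames must not change valid-frame outputs."""
        layer = BiGRU(3, 4, rng=rng)
        lengths = np.array([4])
        x = rng.normal(size=(1, 6, 3)).astype(np.float32)
        y1 = layer.forward(x, lengths)[:, :4]
        x2 = x.copy()
        x2[:, 4:] += 10.0
        y2 = layer.forward(x2, lengths)[:, :4]
        np.testing.assert_allclose(y1, y2, atol=1e-6)


class TestTraining:
    def _toy_data(self, alphabet, n=24, T=256, seed=0):
        """Signals with class-dependent bumps so the mapping is learnable."""
        rng = np.random.default_rng(seed)
        data = []
        for i in range(n):
            tok = alphabet.tokens[i % 2]
            x = rng.normal(0, 0.3, size=T)
            centre = 1.0 if tok == "M0" else -1.0
            x[T // 4 : 3 * T // 4] += centre
            from motifcaller.simulate import SignalRead

            data.append(
                (SignalRead(f"r{i}", x.astype(np.float32), "forward", "b", [tok]), [tok])
            )
        return data

    def test_loss_decreases_and_is_deterministic(self, tiny_alphabet):
        cfg = CallerConfig(
            conv_filters=(4, 4, 8, 8), rnn_layers=1, hidden=8, fc_size=16,
            n_classes=tiny_alphabet.n_classes, epochs=5, batch_size=8, seed=3,
        )
        data = self._toy_data(tiny_alphabet)
        _, hist1 = train(data, cfg, tiny_alphabet)
        _, hist2 = train(data, cfg, tiny_alphabet)
        assert hist1 == hist2
        assert hist1[-1] < hist1[0]

    def test_empty_training_set_rejected(self, tiny_alphabet):
        cfg = CallerConfig(
            conv_filters=(4, 4, 8, 8), rnn_layers=1, hidden=8, fc_size=16,
            n_classes=tiny_alphabet.n_classes,
        )
        with pytest.raises(ValueError):
            train([], cfg, tiny_alphabet)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        tiny_model.save(str(path))
        loaded = MotifCallerModel.load(str(path))
        x = rng.normal(size=960)
        np.testing.assert_allclose(
            forward(tiny_model, x).log_probs, forward(loaded, x).log_probs, atol=1e-7
        )
        assert loaded.alphabet == tiny_model.alphabet

    def test_schema_mismatch_rejected(self, tiny_model, tmp_path):
        import json

        path = tmp_path / "model.npz"
        tiny_model.save(str(path))
        data = dict(np.load(str(path)))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["schema_version"] = 999
        data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(str(path), **data)
        with pytest.raises(ValueError, match="schema"):
            MotifCallerModel.load(str(path))


class TestFinetune:
    def test_zero_epochs_is_identity(self, tiny_model):
        from motifcaller.model import finetune

        model, hist = finetune(tiny_model, [], epochs=0)
        assert model is tiny_model and hist == []

    def test_alphabet_mismatch_rejected(self, tiny_model):
        from motifcaller.model import finetune
        from motifcaller.simulate import SignalRead

        bad = [(SignalRead("r", np.zeros(128, dtype=np.float32), "forward", "b", []), ["ZZZ"])]
        with pytest.raises(ValueError, match="alphabet"):
            finetune(tiny_model, bad, epochs=1)

    def test_adapts_to_shifted_distribution(self, tiny_alphabet):
        """Warm-start training on shifted signals lowers their loss."""
        from motifcaller.ctc import ctc_loss_grad
        from motifcaller.model import finetune

        cfg = CallerConfig(
            conv_filters=(4, 4, 8, 8), rnn_layers=1, hidden=8, fc_size=16,
            n_classes=tiny_alphabet.n_classes, epochs=6, batch_size=8, seed=5,
        )
        original = TestTraining()._toy_data(tiny_alphabet, seed=0)
        model, _ = train(original, cfg, tiny_alphabet)

        # shifted run: extra amplitude noise (a genuinely harder signal regime,
        # not removed by the affine-invariant normalization)
        noise_rng = np.random.default_rng(13)
        shifted = []
        for read, toks in TestTraining()._toy_data(tiny_alphabet, seed=9):
            read.samples = read.samples + noise_rng.normal(
                0, 0.5, size=read.samples.shape
            ).astype(np.float32)
            shifted.append((read, toks))

        def mean_loss(m):
            total = 0.0
            for read, toks in shifted:
                logits, fl = m.forward_batch([read.samples])
                lab = m.alphabet.encode(toks)
                total += ctc_loss_grad(logits[0, : fl[0]], lab, m.alphabet.blank)[0]
            return total / len(shifted)

        before = mean_loss(model)
        model, hist = finetune(model, shifted, epochs=6)
        after = mean_loss(model)
        assert len(hist) == 6
        assert after < before
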