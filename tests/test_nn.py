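"""Gradient correctness and numerical properties of the NumPy layers.

Every layer's analytic backward pass is compared against central finite
differences in float64. The composed encoder/classifier stacks are checked
with directional derivatives (per-element differencing is too noisy for
tiny composite gradients).
"""

import numpy as np
import pytest

from condphage import nn
from condphage.model import ClassifierConfig, ConditionalEncoder, EncoderConfig, SegmentClassifier
from condphage.pretrain import IGNORE_INDEX

RNG = np.random.default_rng(20240917)


def numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        lp = f()
        arr[i] = old - eps
        lm = f()
        arr[i] = old
        g[i] = (lp - lm) / (2 * eps)
    return g


def assert_grads_match(module, loss_fn, tol=1e-5):
    for name, p in module.named_parameters():
        ng = numeric_grad(loss_fn, p.value)
        denom = max(np.abs(ng).max(), np.abs(p.grad).max(), 1e-8)
        rel = np.abs(ng - p.grad).max() / denom
        assert rel < tol, f"{name}: relative gradient error {rel:.2e}"


@pytest.fixture()
def xmask():
    x = RNG.standard_normal((3, 7, 6))
    mask = np.ones((3, 7))
    mask[0, 5:] = 0
    return x, mask


class TestLayerGradients:
    def test_dense(self):
        layer = nn.Dense(5, 4, RNG, dtype=np.float64)
        x = RNG.standard_normal((6, 5))
        w = RNG.standard_normal((6, 4))

        def loss():
            return float((layer.forward(x) * w).sum())

        layer.zero_grad()
        layer.forward(x)
        layer.backward(w.copy())
        assert_grads_match(layer, loss)

    def test_layernorm(self):
        layer = nn.LayerNorm(6, dtype=np.float64)
        layer.gamma.value += RNG.standard_normal(6) * 0.3
        layer.beta.value += RNG.standard_normal(6) * 0.3
        x = RNG.standard_normal((4, 6))
        w = RNG.standard_normal((4, 6))

        def loss():
            return float((layer.forward(x) * w).sum())

        layer.zero_grad()
        layer.forward(x)
        layer.backward(w.copy())
        assert_grads_match(layer, loss)

    def test_layernorm_input_gradient(self):
        layer = nn.LayerNorm(6, dtype=np.float64)
        x = RNG.standard_normal((2, 6))
        w = RNG.standard_normal((2, 6))
        layer.forward(x)
        dx = layer.backward(w.copy())
        ndx = numeric_grad(lambda: float((layer.forward(x) * w).sum()), x)
        assert np.abs(dx - ndx).max() < 1e-7

    def test_attention_with_padding_mask(self, xmask):
        x, mask = xmask
        att = nn.MultiHeadSelfAttention(6, 2, RNG, dtype=np.float64)
        bias = ((1 - mask)[:, None, None, :] * nn.layers.NEG_INF).astype(np.float64)
        w = RNG.standard_normal(x.shape)

        def loss():
            return float((att.forward(x, bias) * w).sum())

        att.zero_grad()
        att.forward(x, bias)
        att.backward(w.copy())
        assert_grads_match(att, loss)

    def test_transformer_block(self, xmask):
        x, mask = xmask
        blk = nn.TransformerBlock(6, 2, 12, 0.0, RNG, dtype=np.float64)
        bias = ((1 - mask)[:, None, None, :] * nn.layers.NEG_INF).astype(np.float64)
        w = RNG.standard_normal(x.shape)

        def loss():
            return float((blk.forward(x, bias) * w).sum())

        blk.zero_grad()
        blk.forward(x, bias)
        blk.backward(w.copy())
        assert_grads_match(blk, loss)

    def test_bilstm(self, xmask):
        x, mask = xmask
        bl = nn.BiLSTMPool(6, 4, RNG, dtype=np.float64)
        w = RNG.standard_normal(8)

        def loss():
            return float((bl.forward(x, mask) @ w).sum())

        bl.zero_grad()
        out = bl.forward(x, mask)
        bl.backward(np.broadcast_to(w, out.shape).copy())
        assert_grads_match(bl, loss)

    def test_bilstm_input_gradient(self, xmask):
        x, mask = xmask
        bl = nn.BiLSTMPool(6, 4, RNG, dtype=np.float64)
        w = RNG.standard_normal(8)
        out = bl.forward(x, mask)
        dx = bl.backward(np.broadcast_to(w, out.shape).copy())
        ndx = numeric_grad(lambda: float((bl.forward(x, mask) @ w).sum()), x)
        assert np.abs(dx - ndx).max() < 1e-7
        # padded timesteps receive no gradient
        assert np.abs(dx[0, 5:]).max() == 0.0


def _directional_check(params, grads, loss, loss0, eps=2e-5):
    """Compare analytic directional derivative with central differences
    along one random direction per parameter tensor."""
    worst = 0.0
    for name, p in params:
        d = np.random.default_rng(len(name)).standard_normal(p.value.shape)
        d /= np.linalg.norm(d) + 1e-12
        old = p.value.copy()
        p.value = old + eps * d
        lp = loss()
        p.value = old - eps * d
        lm = loss()
        p.value = old
        fd = (lp - lm) / (2 * eps)
        an = float((grads[name] * d).sum())
        scale = max(abs(fd), abs(an), 1e-7)
        worst = max(worst, abs(fd - an) / scale)
    return worst


class TestComposedGradients:
    def _models(self):
        rng = np.random.default_rng(3)
        cfg = EncoderConfig(vocab_size=20, num_layers=2, hidden_size=8, num_heads=2,
                            ff_size=16, max_positions=16, dropout=0.0)
        enc = ConditionalEncoder(cfg, rng, dtype=np.float64)
        clf = SegmentClassifier(enc, ClassifierConfig(lstm_hidden=5, mlp_hidden=6),
                                rng, dtype=np.float64)
        ids = rng.integers(0, 20, size=(3, 9))
        mask = np.ones((3, 9), dtype=np.int64)
        mask[0, 6:] = 0
        return enc, clf, ids, mask

    def test_classifier_stack(self):
        _, clf, ids, mask = self._models()
        y = np.array([0, 1, 2])

        def loss():
            return nn.softmax_cross_entropy(clf.logits(ids, mask), y)[0]

        clf.zero_grad()
        logits = clf.logits(ids, mask)
        loss0, dl = nn.softmax_cross_entropy(logits, y)
        clf.backward_from_logits(dl)
        grads = {n: p.grad.copy() for n, p in clf.named_parameters()}
        worst = _directional_check(list(clf.named_parameters()), grads, loss, loss0)
        assert worst < 1e-3

    def test_mlm_stack(self):
        enc, _, ids, mask = self._models()
        targets = np.full(ids.shape, IGNORE_INDEX)
        targets[0, 2], targets[1, 3], targets[2, 1] = 5, 7, 1

        def loss():
            h = enc.hidden_states(ids, mask)
            r, c = np.nonzero(targets != IGNORE_INDEX)
            return nn.softmax_cross_entropy(enc.mlm_head.forward(h[r, c]), targets[r, c])[0]

        enc.zero_grad()
        h = enc.hidden_states(ids, mask)
        r, c = np.nonzero(targets != IGNORE_INDEX)
        logits = enc.mlm_head.forward(h[r, c])
        loss0, dl = nn.softmax_cross_entropy(logits, targets[r, c])
        dg = enc.mlm_head.backward(dl)
        dh = np.zeros_like(h)
        dh[r, c] = dg
        enc.encoder.backward(dh)
        grads = {n: p.grad.copy() for n, p in enc.named_parameters()}
        worst = _directional_check(list(enc.named_parameters()), grads, loss, loss0)
        assert worst < 1e-3


class TestNumericalProperties:
    def test_softmax_cross_entropy_matches_log_softmax(self):
        logits = RNG.standard_normal((5, 4))
        y = np.array([0, 3, 1, 2, 2])
        loss, _ = nn.softmax_cross_entropy(logits, y)
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        assert np.isclose(loss, -logp[np.arange(5), y].mean())

    def test_padding_does_not_change_nonpad_representations(self):
        cfg = EncoderConfig(vocab_size=30, num_layers=2, hidden_size=16, num_heads=2,
                            ff_size=32, max_positions=32, dropout=0.0)
        enc = ConditionalEncoder(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        ids_short = rng.integers(0, 30, size=(2, 10)).astype(np.int32)
        mask_short = np.ones((2, 10), dtype=np.int32)
        mask_short[1, 8:] = 0
        ids_long = np.zeros((2, 20), dtype=np.int32)
        ids_long[:, :10] = ids_short
        mask_long = np.zeros((2, 20), dtype=np.int32)
        mask_long[:, :10] = mask_short
        h_short = enc.hidden_states(ids_short, mask_short)
        h_long = enc.hidden_states(ids_long, mask_long)
        np.testing.assert_allclose(h_long[:, :10][mask_short.astype(bool)],
                                   h_short[mask_short.astype(bool)], atol=2e-5)

    def test_dropout_inference_is_identity_and_training_scales(self):
        drop = nn.Dropout(0.5)
        x = np.ones((100, 100), dtype=np.float32)
        assert drop.forward(x, train=False) is x
        y = drop.forward(x, train=True, rng=np.random.default_rng(0))
        kept = y > 0
        assert 0.4 < kept.mean() < 0.6
        assert np.allclose(y[kept], 2.0)  # inverted scaling

    def test_lr_schedule_warmup_then_decay(self):
        lrs = [nn.linear_warmup_decay(s, 1.0, 10, 100) for s in range(100)]
        assert lrs[0] == pytest.approx(0.1)
        assert lrs[9] == pytest.approx(1.0)
        assert lrs[50] < lrs[20]
        assert min(lrs) >= 0.1  # floored
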