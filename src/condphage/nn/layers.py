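"""Neural-network building blocks on plain NumPy arrays.

Every layer follows one contract: ``forward`` caches whatever its matching
``backward`` needs, ``backward`` accumulates parameter gradients in place
and returns the gradient with respect to its input. Gradients are verified
against central finite differences in the test suite, so the algebra here
is load-bearing — change it only together with the gradient checks.

float32 is the working precision; float64 is supported for gradient
checking.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np

NEG_INF = -1e9  # additive attention bias for padded key positions


class Parameter:
    """A trainable array with an in-place accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def shape(self):
        return self.value.shape


class Module:
    """Base class with explicit parameter/submodule registration."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}

    def param(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(value)
        self._params[name] = p
        return p

    def child(self, name: str, module: "Module"):
        self._modules[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def zero_grad(self) -> None:
        for _, p in self.named_parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            if p.value.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.value.shape} vs {state[name].shape}"
                )
            p.value[...] = state[name]


def init_normal(rng: np.random.Generator, shape, std: float = 0.02, dtype=np.float32):
    return (rng.standard_normal(shape) * std).astype(dtype)


class Dense(Module):
    """Affine map over the last axis: y = x @ W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.W = self.param("W", init_normal(rng, (d_in, d_out), dtype=dtype))
        self.b = self.param("b", np.zeros(d_out, dtype=dtype))
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class Embedding(Module):
    """Id → vector lookup table."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.W = self.param("W", init_normal(rng, (n, dim), dtype=dtype))
        self._ids: Optional[np.ndarray] = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.W.value[ids]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.W.grad, self._ids, dy)


class LayerNorm(Module):
    """Normalization over the last axis with learned scale/shift."""

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.param("gamma", np.ones(dim, dtype=dtype))
        self.beta = self.param("beta", np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Dropout(Module):
    """Inverted dropout; identity when p == 0 or not training."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask: Optional[np.ndarray] = None

    def forward(self, x, train: bool = False, rng: Optional[np.random.Generator] = None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit — the position-wise activation.

    Chosen over the smooth GELU of the original BERT recipe: on CPU the
    transcendental evaluation over [B, L, ff] tensors dominates the
    feed-forward cost, and for the model sizes this package trains the
    activation choice is not performance-relevant.
    """
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. ``logits``.

    ``logits``: [N, C]; ``targets``: [N] integer class indices.
    """
    n = logits.shape[0]
    if n == 0:
        return 0.0, np.zeros_like(logits)
    z = logits - logits.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    logp = z[np.arange(n), targets] - logsumexp
    loss = float(-logp.mean())
    probs = softmax(logits)
    dlogits = probs
    dlogits[np.arange(n), targets] -= 1.0
    dlogits /= n
    return loss, dlogits


class FeedForward(Module):
    """Position-wise two-layer MLP with ReLU."""

    def __init__(self, hidden: int, ff: int, rng, dtype=np.float32):
        super().__init__()
        self.d1 = self.child("d1", Dense(hidden, ff, rng, dtype))
        self.d2 = self.child("d2", Dense(ff, hidden, rng, dtype))

    def forward(self, x):
        self._pre = self.d1.forward(x)
        return self.d2.forward(relu(self._pre))

    def backward(self, dy):
        dg = self.d2.backward(dy)
        return self.d1.backward(dg * relu_grad(self._pre))


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with an additive key mask."""

    def __init__(self, hidden: int, n_heads: int, rng, dtype=np.float32):
        super().__init__()
        if hidden % n_heads != 0:
            raise ValueError(f"hidden={hidden} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = hidden // n_heads
        self.qkv = self.child("qkv", Dense(hidden, 3 * hidden, rng, dtype))
        self.out = self.child("out", Dense(hidden, hidden, rng, dtype))

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, l, _ = x.shape
        return x.reshape(b, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, l, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, l, h * d)

    def forward(self, x: np.ndarray, key_bias: np.ndarray) -> np.ndarray:
        """``key_bias``: [B, 1, 1, L] additive scores (0 keep, NEG_INF drop)."""
        qkv = self.qkv.forward(x)
        h = x.shape[-1]
        q = self._split(qkv[..., :h])
        k = self._split(qkv[..., h : 2 * h])
        v = self._split(qkv[..., 2 * h :])
        scale = 1.0 / math.sqrt(self.d_head)
        # the [B, H, L, L] score tensor dominates time and memory at long L;
        # normalize it in place rather than allocating fresh copies
        scores = q @ k.transpose(0, 1, 3, 2)
        scores *= scale
        scores += key_bias
        scores -= scores.max(axis=-1, keepdims=True)
        np.exp(scores, out=scores)
        scores /= scores.sum(axis=-1, keepdims=True)
        attn = scores
        ctx = attn @ v
        self._cache = (q, k, v, attn, scale)
        return self.out.forward(self._merge(ctx))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        dctx = self._split(self.out.backward(dy))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward, reusing dattn as the dscores buffer
        dattn -= (dattn * attn).sum(axis=-1, keepdims=True)
        dattn *= attn
        dscores = dattn
        dq = (dscores @ k) * scale
        dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale
        dqkv = np.concatenate(
            [self._merge(dq), self._merge(dk), self._merge(dv)], axis=-1
        )
        return self.qkv.backward(dqkv)


class TransformerBlock(Module):
    """Post-norm encoder block: attention and feed-forward, each with a
    residual connection followed by layer normalization."""

    def __init__(self, hidden: int, n_heads: int, ff: int, dropout: float, rng, dtype=np.float32):
        super().__init__()
        self.attn = self.child("attn", MultiHeadSelfAttention(hidden, n_heads, rng, dtype))
        self.ln1 = self.child("ln1", LayerNorm(hidden, dtype))
        self.ffn = self.child("ffn", FeedForward(hidden, ff, rng, dtype))
        self.ln2 = self.child("ln2", LayerNorm(hidden, dtype))
        self.drop1 = self.child("drop1", Dropout(dropout))
        self.drop2 = self.child("drop2", Dropout(dropout))

    def forward(self, x, key_bias, train=False, rng=None):
        a = self.drop1.forward(self.attn.forward(x, key_bias), train, rng)
        h = self.ln1.forward(x + a)
        f = self.drop2.forward(self.ffn.forward(h), train, rng)
        return self.ln2.forward(h + f)

    def backward(self, dy):
        dhf = self.ln2.backward(dy)
        dh = dhf + self.ffn.backward(self.drop2.backward(dhf))
        dxa = self.ln1.backward(dh)
        return dxa + self.attn.backward(self.drop1.backward(dxa))


class TransformerEncoder(Module):
    """Token+position embeddings followed by a stack of encoder blocks."""

    def __init__(
        self,
        vocab_size: int,
        max_positions: int,
        hidden: int,
        n_layers: int,
        n_heads: int,
        ff: int,
        dropout: float,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        self.max_positions = max_positions
        self.dtype = dtype
        self.tok = self.child("tok", Embedding(vocab_size, hidden, rng, dtype))
        self.pos = self.child("pos", Embedding(max_positions, hidden, rng, dtype))
        self.emb_ln = self.child("emb_ln", LayerNorm(hidden, dtype))
        self.emb_drop = self.child("emb_drop", Dropout(dropout))
        self.blocks = [
            self.child(f"block{i}", TransformerBlock(hidden, n_heads, ff, dropout, rng, dtype))
            for i in range(n_layers)
        ]

    def forward(
        self,
        ids: np.ndarray,
        attention_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        b, l = ids.shape
        if l > self.max_positions:
            raise ValueError(f"sequence length {l} exceeds max_positions={self.max_positions}")
        pos_ids = np.broadcast_to(np.arange(l), (b, l))
        x = self.tok.forward(ids) + self.pos.forward(pos_ids)
        x = self.emb_drop.forward(self.emb_ln.forward(x), train, rng)
        key_bias = ((1 - attention_mask)[:, None, None, :] * NEG_INF).astype(self.dtype)
        for block in self.blocks:
            x = block.forward(x, key_bias, train, rng)
        return x

    def backward(self, dh: np.ndarray) -> None:
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        dh = self.emb_ln.backward(self.emb_drop.backward(dh))
        self.tok.backward(dh)
        self.pos.backward(dh)
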