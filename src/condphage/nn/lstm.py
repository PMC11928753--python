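"""LSTM layers with full backpropagation through time.

The classifier head runs a bidirectional LSTM over the encoder's
per-position representations and pools the two final hidden states.
Padded positions are handled by a masked state update: where the mask is
0 the previous hidden/cell state is carried through unchanged, so the
"final" forward state is the state at the last real token.

The input projection ``x @ Wx`` and all weight-gradient contractions are
batched over time; only the recurrent ``h @ Wh`` chain runs in the
per-timestep loop.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, init_normal


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # single-pass logistic; exp overflow for very negative inputs saturates
    # to exactly 0, which is the correct limit
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class LSTM(Module):
    """Single-direction LSTM returning the final (mask-aware) hidden state.

    ``reverse=True`` processes the sequence right-to-left, so its final
    state summarizes the sequence as read from the end.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        self.reverse = reverse
        self.Wx = self.param("Wx", init_normal(rng, (d_in, 4 * hidden), dtype=dtype))
        self.Wh = self.param("Wh", init_normal(rng, (hidden, 4 * hidden), dtype=dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.b = self.param("b", b)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """``x``: [B, L, D]; ``mask``: [B, L] 0/1. Returns final h [B, H]."""
        if self.reverse:
            x = x[:, ::-1]
            mask = mask[:, ::-1]
        b, l, _ = x.shape
        hd = self.hidden
        xw = x @ self.Wx.value + self.b.value  # [B, L, 4H], batched over time
        m = np.ascontiguousarray(mask, dtype=x.dtype)[..., None]
        h = np.zeros((b, hd), dtype=x.dtype)
        c = np.zeros((b, hd), dtype=x.dtype)
        gates = np.empty((b, l, 4 * hd), dtype=x.dtype)  # i, f, g, o after nonlinearity
        tcs = np.empty((b, l, hd), dtype=x.dtype)
        h_prev = np.empty((b, l, hd), dtype=x.dtype)
        c_prev = np.empty((b, l, hd), dtype=x.dtype)
        for t in range(l):
            z = xw[:, t] + h @ self.Wh.value
            i = _sigmoid(z[:, :hd])
            f = _sigmoid(z[:, hd : 2 * hd])
            g = np.tanh(z[:, 2 * hd : 3 * hd])
            o = _sigmoid(z[:, 3 * hd :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            gates[:, t, :hd] = i
            gates[:, t, hd : 2 * hd] = f
            gates[:, t, 2 * hd : 3 * hd] = g
            gates[:, t, 3 * hd :] = o
            tcs[:, t] = tc
            h_prev[:, t] = h
            c_prev[:, t] = c
            mt = m[:, t]
            h = mt * h_new + (1.0 - mt) * h
            c = mt * c_new + (1.0 - mt) * c
        self._cache = (x, m, gates, tcs, h_prev, c_prev)
        return h

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        """Backprop from the final hidden state; returns dx [B, L, D]."""
        x, m, gates, tcs, h_prev, c_prev = self._cache
        b, l, _ = x.shape
        hd = self.hidden
        dz_all = np.empty((b, l, 4 * hd), dtype=x.dtype)
        dh = dh_final.astype(x.dtype, copy=True)
        dc = np.zeros_like(dh)
        WhT = self.Wh.value.T
        for t in range(l - 1, -1, -1):
            i = gates[:, t, :hd]
            f = gates[:, t, hd : 2 * hd]
            g = gates[:, t, 2 * hd : 3 * hd]
            o = gates[:, t, 3 * hd :]
            tc = tcs[:, t]
            mt = m[:, t]
            dh_new = mt * dh
            dc_new = mt * dc + dh_new * o * (1.0 - tc * tc)
            do = dh_new * tc
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev[:, t]
            dc = dc_new * f + (1.0 - mt) * dc
            dz = dz_all[:, t]
            dz[:, :hd] = di * i * (1 - i)
            dz[:, hd : 2 * hd] = df * f * (1 - f)
            dz[:, 2 * hd : 3 * hd] = dg * (1 - g * g)
            dz[:, 3 * hd :] = do * o * (1 - o)
            dh = (1.0 - mt) * dh + dz @ WhT
        dz2 = dz_all.reshape(-1, 4 * hd)
        self.Wx.grad += x.reshape(-1, x.shape[-1]).T @ dz2
        self.Wh.grad += h_prev.reshape(-1, hd).T @ dz2
        self.b.grad += dz2.sum(axis=0)
        dx = dz_all @ self.Wx.value.T
        if self.reverse:
            dx = dx[:, ::-1]
        return dx


class BiLSTMPool(Module):
    """Bidirectional LSTM pooled as [final forward ; final backward] state."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fwd = self.child("fwd", LSTM(d_in, hidden, rng, reverse=False, dtype=dtype))
        self.bwd = self.child("bwd", LSTM(d_in, hidden, rng, reverse=True, dtype=dtype))
        self.hidden = hidden

    @property
    def out_dim(self) -> int:
        return 2 * self.hidden

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x, mask)
        hb = self.bwd.forward(x, mask)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dpooled: np.ndarray) -> np.ndarray:
        hd = self.hidden
        dxf = self.fwd.backward(dpooled[:, :hd])
        dxb = self.bwd.backward(dpooled[:, hd:])
        return dxf + dxb
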