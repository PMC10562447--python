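"""Neural building blocks used by the generator, critic, and predictor.

All layers operate on (batch, length, channels) tensors from
:mod:`seedflank.autodiff`.  Initialization is seeded through a
``numpy.random.Generator`` passed at construction, so model builds are
deterministic.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad


class Module:
    """Base class: tracks parameters of itself and registered submodules."""

    def _modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        yield x

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, ad.Tensor) and v.requires_grad:
                params.append(v)
        for m in self._modules():
            params.extend(m.parameters())
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


class Dense(Module):
    def __init__(self, n_in, n_out, rng):
        self.W = ad.parameter(_glorot(rng, (n_in, n_out)))
        self.b = ad.parameter(np.zeros(n_out))

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.W), self.b)


class Conv1d(Module):
    """Same-padded 1-D convolution on (B, L, C_in) via im2col + matmul."""

    def __init__(self, c_in, c_out, kernel, rng):
        self.kernel = int(kernel)
        self.c_in, self.c_out = c_in, c_out
        self.W = ad.parameter(_glorot(rng, (self.kernel * c_in, c_out)))
        self.b = ad.parameter(np.zeros(c_out))

    def __call__(self, x):
        B, L, C = x.shape
        k = self.kernel
        if k == 1:
            return ad.add(ad.matmul(x, self.W), self.b)
        left = k // 2
        right = k - 1 - left
        pads = []
        if left:
            pads.append(ad.Tensor(np.zeros((B, left, C))))
        pads.append(x)
        if right:
            pads.append(ad.Tensor(np.zeros((B, right, C))))
        xp = ad.concat(pads, axis=1)
        idx = np.arange(L)[:, None] + np.arange(k)[None, :]  # (L, k)
        windows = xp[(slice(None), idx)]                      # (B, L, k, C)
        flat = ad.reshape(windows, (B, L, k * C))
        return ad.add(ad.matmul(flat, self.W), self.b)


class MultiHeadAttention(Module):
    """Self-attention, concat of heads, no output projection.

    head_i = softmax(X Q_i (X K_i)^T / sqrt(d_k)) X V_i — note the scaling is
    by the full channel count d_k, not the per-head width.
    """

    def __init__(self, d_k, heads, rng):
        if d_k % heads:
            raise ValueError("heads must divide d_k")
        self.d_k, self.heads = d_k, heads
        self.d_head = d_k // heads
        self.Wq = ad.parameter(_glorot(rng, (d_k, d_k)))
        self.Wk = ad.parameter(_glorot(rng, (d_k, d_k)))
        self.Wv = ad.parameter(_glorot(rng, (d_k, d_k)))

    def _split(self, t, B, L):
        t = ad.reshape(t, (B, L, self.heads, self.d_head))
        return ad.transpose(t, (0, 2, 1, 3))  # (B, o, L, d_head)

    def __call__(self, x):
        B, L, _ = x.shape
        q = self._split(ad.matmul(x, self.Wq), B, L)
        k = self._split(ad.matmul(x, self.Wk), B, L)
        v = self._split(ad.matmul(x, self.Wv), B, L)
        scores = ad.div(ad.matmul(q, ad.swap_last(k)), np.sqrt(self.d_k))
        attn = ad.softmax(scores, axis=-1)
        out = ad.matmul(attn, v)  # (B, o, L, d_head)
        out = ad.transpose(out, (0, 2, 1, 3))
        return ad.reshape(out, (B, L, self.d_k))


class ResBlock(Module):
    """Channel-preserving residual block: conv-relu-conv plus skip."""

    def __init__(self, channels, kernel, rng):
        self.conv1 = Conv1d(channels, channels, kernel, rng)
        self.conv2 = Conv1d(channels, channels, kernel, rng)

    def __call__(self, x):
        h = ad.relu(self.conv1(x))
        h = self.conv2(h)
        return ad.relu(ad.add(x, h))


class LSTM(Module):
    """Single-layer LSTM over (B, L, C); optionally bidirectional."""

    def __init__(self, c_in, hidden, rng, bidirectional=True):
        self.hidden = hidden
        self.bidirectional = bidirectional
        self.fwd = _LSTMCell(c_in, hidden, rng)
        self.bwd = _LSTMCell(c_in, hidden, rng) if bidirectional else None

    def __call__(self, x):
        B, L, _ = x.shape
        out_f = self.fwd.run(x, range(L))
        if not self.bidirectional:
            return out_f
        out_b = self.bwd.run(x, range(L - 1, -1, -1), reverse=True)
        return ad.concat([out_f, out_b], axis=2)

    @property
    def out_channels(self):
        return self.hidden * (2 if self.bidirectional else 1)


class _LSTMCell(Module):
    def __init__(self, c_in, hidden, rng):
        self.hidden = hidden
        self.Wx = ad.parameter(_glorot(rng, (c_in, 4 * hidden)))
        self.Wh = ad.parameter(_glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = ad.parameter(b)

    def run(self, x, order, reverse=False):
        B, L, _ = x.shape
        H = self.hidden
        h = ad.Tensor(np.zeros((B, H)))
        c = ad.Tensor(np.zeros((B, H)))
        outs = [None] * L
        for t in order:
            xt = x[(slice(None), t)]
            gates = ad.add(ad.add(ad.matmul(xt, self.Wx), ad.matmul(h, self.Wh)), self.b)
            i = ad.sigmoid(gates[(slice(None), slice(0, H))])
            f = ad.sigmoid(gates[(slice(None), slice(H, 2 * H))])
            g = ad.tanh(gates[(slice(None), slice(2 * H, 3 * H))])
            o = ad.sigmoid(gates[(slice(None), slice(3 * H, 4 * H))])
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(c))
            outs[t] = ad.reshape(h, (B, 1, H))
        return ad.concat(outs, axis=1)


def global_avg_pool(x):
    """Mean over the length axis of (B, L, C)."""
    return ad.tmean(x, axis=1)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, ad.Tensor) else g
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def save_checkpoint(path, model: Module, config: dict) -> None:
    """Single-file archive of weights plus config (npz, schema v1)."""
    import json

    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __schema__=np.array(1), __config__=np.array(json.dumps(config)),
             **arrays)


def load_checkpoint(path):
    """Return (config dict, list of weight arrays)."""
    import json

    with np.load(path, allow_pickle=False) as z:
        config = json.loads(str(z["__config__"]))
        n = len([k for k in z.files if k.startswith("p")])
        arrays = [z[f"p{i}"] for i in range(n)]
    return config, arrays
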