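"""Minimal NumPy neural-network layers with explicit backward passes.

Each layer owns ``params`` and ``grads`` dicts keyed by name; ``forward``
caches whatever the matching ``backward`` needs.  Everything runs in float64
on one CPU and is bit-deterministic given the seeding RNG.
"""

from __future__ import annotations

import numpy as np

from .mask import CrossKernelMask, conv2d_backward, conv2d_forward


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def parameters(self):
        return [(self, k) for k in self.params]


class MaskedConv2d(Layer):
    """2-D convolution whose kernels are constrained to a cross mask.

    Weights outside the mask are zero at initialisation and their gradients
    are zeroed in ``backward``, so they remain exactly zero through any
    optimiser trajectory.  ``mask=None`` gives a dense convolution (the
    plain-CNN ablation).
    """

    def __init__(self, in_ch, out_ch, kernel_size, rng,
                 mask: CrossKernelMask | None = None, stride=1, padding=0):
        super().__init__()
        kh, kw = kernel_size
        self.mask = mask
        self.stride, self.padding = stride, padding
        fan_in = (mask.n_active if mask is not None else kh * kw) * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw))
        if mask is not None:
            w *= mask.mask[None, None]
        self.params = {"w": w, "b": np.zeros(out_ch)}

    @property
    def _m(self):
        return None if self.mask is None else self.mask.mask

    def forward(self, x):
        self._x = x
        return conv2d_forward(x, self.params["w"], self.params["b"],
                              stride=self.stride, padding=self.padding,
                              mask=self._m)

    def backward(self, dout):
        dx, dw, db = conv2d_backward(self._x, self.params["w"], dout,
                                     stride=self.stride, padding=self.padding,
                                     mask=self._m)
        if self.mask is not None:
            dw *= self.mask.mask[None, None]
        self.grads = {"w": dw, "b": db}
        return dx

    def remask(self):
        """Force masked-out weights back to exactly zero."""
        if self.mask is not None:
            self.params["w"] *= self.mask.mask[None, None]


class BatchNorm2d(Layer):
    def __init__(self, n_ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout):
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        if not self.training:
            return (dout * self.params["gamma"][None, :, None, None]
                    / self._std[None, :, None, None])
        dxhat = dout * self.params["gamma"][None, :, None, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3),
                                                       keepdims=True))
        return dx / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dout):
        return dout * self._pos


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = x.shape
        xc = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        xc = xc.transpose(0, 1, 2, 4, 3, 5)        # (n, c, h2, w2, 2, 2)
        out = xc.max(axis=(4, 5))
        # break ties deterministically: route gradient to the first max only
        flat = (xc == out[..., None, None]).reshape(n, c, h2, w2, 4)
        cum = np.cumsum(flat, axis=-1)
        self._first = (cum == 1) & flat
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dxw = (self._first * dout[:, :, :, :, None]).reshape(n, c, h2, w2, 2, 2)
        dx = np.zeros((n, c, h, w))
        dx[:, :, :h2 * 2, :w2 * 2] = dxw.transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2 * 2, w2 * 2)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.params = {"w": w, "b": np.zeros(d_out)}

    def forward(self, x):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"w": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if not self.training or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTMDirection(Layer):
    """One direction of an LSTM over a scalar-per-step sequence.

    Input (n, T); standard gate equations with gate order (i, f, g, o);
    returns the full hidden-state sequence (n, T, H).
    """

    def __init__(self, hidden, rng, d_in=1):
        super().__init__()
        h = hidden
        s = 1.0 / np.sqrt(h)
        self.hidden = h
        self.params = {
            "wx": rng.uniform(-s, s, size=(d_in, 4 * h)),
            "wh": rng.uniform(-s, s, size=(h, 4 * h)),
            "b": np.zeros(4 * h),
        }
        # forget-gate bias of 1 for stable long-sequence training
        self.params["b"][h:2 * h] = 1.0

    def forward(self, x):
        n, T = x.shape[0], x.shape[1]
        h = self.hidden
        x3 = x[..., None] if x.ndim == 2 else x
        self._x3 = x3
        xw = np.tensordot(x3, self.params["wx"], axes=([2], [0]))  # (n,T,4h)
        gi = np.empty((n, T, h)); gf = np.empty((n, T, h))
        gg = np.empty((n, T, h)); go = np.empty((n, T, h))
        cs = np.empty((n, T, h)); hs = np.empty((n, T, h))
        hp = np.zeros((n, h)); cp = np.zeros((n, h))
        wh, b = self.params["wh"], self.params["b"]
        for t in range(T):
            a = xw[:, t] + hp @ wh + b
            i = _sigmoid(a[:, :h]); f = _sigmoid(a[:, h:2 * h])
            g = np.tanh(a[:, 2 * h:3 * h]); o = _sigmoid(a[:, 3 * h:])
            cp = f * cp + i * g
            hp = o * np.tanh(cp)
            gi[:, t], gf[:, t], gg[:, t], go[:, t] = i, f, g, o
            cs[:, t], hs[:, t] = cp, hp
        self._cache = (gi, gf, gg, go, cs, hs)
        return hs

    def backward(self, dhs):
        """dhs: gradient w.r.t. the full hidden sequence (n, T, H)."""
        gi, gf, gg, go, cs, hs = self._cache
        n, T, h = hs.shape
        wh = self.params["wh"]
        dwx = np.zeros_like(self.params["wx"])
        dwh = np.zeros_like(wh)
        db = np.zeros_like(self.params["b"])
        dx3 = np.zeros_like(self._x3)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            dh = dhs[:, t] + dh_next
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((n, h))
            tc = np.tanh(cs[:, t])
            do = dh * tc
            dc = dh * go[:, t] * (1 - tc * tc) + dc_next
            di = dc * gg[:, t]
            dg = dc * gi[:, t]
            df = dc * c_prev
            dc_next = dc * gf[:, t]
            da = np.concatenate([
                di * gi[:, t] * (1 - gi[:, t]),
                df * gf[:, t] * (1 - gf[:, t]),
                dg * (1 - gg[:, t] * gg[:, t]),
                do * go[:, t] * (1 - go[:, t]),
            ], axis=1)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((n, h))
            dwx += self._x3[:, t].T @ da
            dwh += h_prev.T @ da
            db += da.sum(axis=0)
            dx3[:, t] = da @ self.params["wx"].T
            dh_next = da @ wh.T
        self.grads = {"wx": dwx, "wh": dwh, "b": db}
        return dx3


class BiLSTM(Layer):
    """Bidirectional LSTM reducing a (n, T) sequence to (n, 2H).

    ``reduce='last'`` concatenates the forward pass's final hidden state
    with the backward pass's final state (its state after consuming the
    first time step); ``reduce='mean'`` averages the concatenated per-step
    states over time.
    """

    def __init__(self, hidden, rng, reduce="last"):
        if reduce not in ("last", "mean"):
            raise ValueError("reduce must be 'last' or 'mean'")
        self.reduce = reduce
        self.hidden = hidden
        self.fwd = LSTMDirection(hidden, rng)
        self.bwd = LSTMDirection(hidden, rng)
        super().__init__()

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    @property
    def training(self):
        return self.fwd.training

    @training.setter
    def training(self, v):
        self.fwd.training = v
        self.bwd.training = v

    def forward(self, x):
        self._T = x.shape[1]
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])
        self._hf, self._hb = hf, hb
        if self.reduce == "last":
            return np.concatenate([hf[:, -1], hb[:, -1]], axis=1)
        return np.concatenate([hf.mean(axis=1), hb.mean(axis=1)], axis=1)

    def backward(self, dout):
        h = self.hidden
        n, T = dout.shape[0], self._T
        dhf = np.zeros((n, T, h))
        dhb = np.zeros((n, T, h))
        if self.reduce == "last":
            dhf[:, -1] = dout[:, :h]
            dhb[:, -1] = dout[:, h:]
        else:
            dhf += dout[:, None, :h] / T
            dhb += dout[:, None, h:] / T
        dxf = self.fwd.backward(dhf)
        dxb = self.bwd.backward(dhb)
        dx = dxf[..., 0] + dxb[..., 0][:, ::-1]
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)
        super().__init__()

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend(lay.parameters())
        return out

    @property
    def training(self):
        return all(l.training for l in self.layers)

    @training.setter
    def training(self, v):
        for lay in self.layers:
            lay.training = v

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError(
            f"labels must lie in [0, {probs.shape[1]}), got "
            f"[{labels.min()}, {labels.max()}]")
    p = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p, 1e-300, None)).mean())


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits."""
    g = probs.copy()
    g[np.arange(len(labels)), np.asarray(labels, int)] -= 1.0
    return g / len(labels)
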