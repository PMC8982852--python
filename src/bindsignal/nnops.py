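"""Minimal NumPy neural-network layers with explicit backward passes.

All layers operate on channels-first batches ``(N, C, L)``.  Each layer
caches what its backward pass needs during ``forward`` and exposes its
parameters and accumulated gradients through ``params`` / ``grads``
dictionaries keyed by short names; a model namespaces these keys.

Only what the signal-regression architecture needs is implemented:
same-padded 1-D convolution, ReLU, non-overlapping max pooling, inverted
dropout, batch normalization, bilinear (linear in 1-D) upsampling, a
bidirectional GRU, and global average pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot_uniform",
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "BatchNorm1d",
    "BilinearUpsample1d",
    "GRUDirection",
    "BiGRU",
    "global_average_context",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv1d(Layer):
    """Stride-1 cross-correlation with symmetric zero padding ("same")."""

    def __init__(self, in_ch, out_ch, kernel, rng=None, dtype=np.float32):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        if rng is None:
            rng = np.random.default_rng(0)
        self.params["W"] = glorot_uniform(
            rng, (out_ch, in_ch, kernel), in_ch * kernel, out_ch * kernel, dtype
        )
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        N, C, L = x.shape
        k, pad = self.kernel, self.kernel // 2
        W = self.params["W"]
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # same-padded conv as k shifted (O,C)@(N,C,L) matmuls: avoids the
        # cache-hostile im2col transpose copy
        out = np.matmul(W[:, :, 0], xpad[:, :, 0:L])
        for j in range(1, k):
            out += np.matmul(W[:, :, j], xpad[:, :, j : j + L])
        out += self.params["b"][:, None]
        self._cache = (xpad, x.shape)
        return out

    def backward(self, dout):
        xpad, (N, C, L) = self._cache
        k, pad = self.kernel, self.kernel // 2
        W, dW = self.params["W"], self.grads["W"]
        self.grads["b"] += dout.sum(axis=(0, 2))
        # hoist the expensive (N,O,L)->(O,N*L) transpose out of the j loop
        doutT = np.ascontiguousarray(dout.transpose(1, 0, 2)).reshape(self.out_ch, N * L)
        xpadT = np.ascontiguousarray(xpad.transpose(0, 2, 1))  # N, Lp, C
        dxpad = np.zeros_like(xpad)
        for j in range(k):
            cols = xpadT[:, j : j + L, :].reshape(N * L, C)
            dW[:, :, j] += doutT @ cols
            dxpad[:, :, j : j + L] += np.matmul(W[:, :, j].T, dout)
        return dxpad[:, :, pad : pad + L]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; input length must be divisible."""

    def __init__(self, pool):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        N, C, L = x.shape
        if L % self.pool != 0:
            raise ValueError(
                f"length {L} not divisible by pool size {self.pool}; pad the input"
            )
        xr = x.reshape(N, C, L // self.pool, self.pool)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, dout):
        N, C, L = self._shape
        dxr = np.zeros((N, C, L // self.pool, self.pool), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=3)
        return dxr.reshape(N, C, L)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / np.asarray(keep, dtype=x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, L) with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        self._cache = (xhat, inv, x.shape)
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, dout):
        xhat, inv, (N, C, L) = self._cache
        m = N * L
        dgamma = (dout * xhat).sum(axis=(0, 2))
        dbeta = dout.sum(axis=(0, 2))
        self.grads["gamma"] += dgamma
        self.grads["beta"] += dbeta
        # standard batch-statistics backward, reusing dgamma/dbeta sums
        coeff = (self.params["gamma"] * inv).astype(dout.dtype)
        dx = dout - (dbeta / m)[:, None] - xhat * (dgamma / m)[:, None]
        dx *= coeff[:, None]
        return dx


class BilinearUpsample1d(Layer):
    """Linear interpolation upsampling by an integer factor.

    Uses the align_corners=False convention: output position i samples
    input coordinate (i + 0.5)/s - 0.5, clamped (edge replication).
    As a fixed linear map its backward is the transpose scatter.
    """

    def __init__(self, scale):
        super().__init__()
        if scale < 1:
            raise ValueError("scale must be >= 1")
        self.scale = scale
        self._maps: dict[int, tuple] = {}

    def _map(self, T):
        if T not in self._maps:
            coords = (np.arange(T * self.scale) + 0.5) / self.scale - 0.5
            coords = np.clip(coords, 0, T - 1)
            i0 = np.floor(coords).astype(np.int64)
            i1 = np.minimum(i0 + 1, T - 1)
            w1 = coords - i0
            # scatter plan for backward: i0/i1 are sorted, so group runs of
            # equal index and accumulate with add.reduceat
            u0, s0 = np.unique(i0, return_index=True)
            u1, s1 = np.unique(i1, return_index=True)
            self._maps[T] = (i0, i1, 1.0 - w1, w1, (u0, s0), (u1, s1))
        return self._maps[T]

    def forward(self, x, training=False):
        T = x.shape[2]
        i0, i1, w0, w1, _, _ = self._map(T)
        self._T = T
        return x[:, :, i0] * w0 + x[:, :, i1] * w1

    def backward(self, dout):
        i0, i1, w0, w1, (u0, s0), (u1, s1) = self._map(self._T)
        dx = np.zeros(dout.shape[:2] + (self._T,), dtype=dout.dtype)
        dx[:, :, u0] += np.add.reduceat(dout * w0, s0, axis=2)
        dx[:, :, u1] += np.add.reduceat(dout * w1, s1, axis=2)
        return dx


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GRUDirection(Layer):
    """One direction of a GRU, h_0 = 0, no bias terms.

        r_t = sigmoid(W_r x_t + U_r h_{t-1})
        z_t = sigmoid(W_z x_t + U_z h_{t-1})
        hcand_t = tanh(W x_t + U (r_t * h_{t-1}))
        h_t = (1 - z_t) * h_{t-1} + z_t * hcand_t
    """

    WEIGHT_NAMES = ("W_r", "U_r", "W_z", "U_z", "W", "U")

    def __init__(self, in_dim, hidden, rng=None, dtype=np.float32):
        super().__init__()
        self.in_dim, self.hidden = in_dim, hidden
        if rng is None:
            rng = np.random.default_rng(0)
        for name in ("W_r", "W_z", "W"):
            self.params[name] = glorot_uniform(
                rng, (hidden, in_dim), in_dim, hidden, dtype
            )
        for name in ("U_r", "U_z", "U"):
            self.params[name] = glorot_uniform(
                rng, (hidden, hidden), hidden, hidden, dtype
            )
        self.zero_grad()

    def forward(self, x, training=False):
        """x: (N, C, T) -> h: (N, H, T)."""
        N, C, T = x.shape
        if T == 0:
            raise ValueError("GRU input must have at least one time step")
        p = self.params
        h_prev = np.zeros((N, self.hidden), dtype=x.dtype)
        hs = np.empty((N, self.hidden, T), dtype=x.dtype)
        cache = []
        for t in range(T):
            xt = x[:, :, t]
            r = _sigmoid(xt @ p["W_r"].T + h_prev @ p["U_r"].T)
            z = _sigmoid(xt @ p["W_z"].T + h_prev @ p["U_z"].T)
            rh = r * h_prev
            hc = np.tanh(xt @ p["W"].T + rh @ p["U"].T)
            h = (1.0 - z) * h_prev + z * hc
            cache.append((xt, h_prev, r, z, rh, hc))
            hs[:, :, t] = h
            h_prev = h
        self._cache = cache
        self._x_shape = x.shape
        return hs

    def backward(self, dh_out):
        """dh_out: (N, H, T) gradient w.r.t. every output step."""
        N, C, T = self._x_shape
        p, g = self.params, self.grads
        dx = np.zeros((N, C, T), dtype=dh_out.dtype)
        dh_next = np.zeros((N, self.hidden), dtype=dh_out.dtype)
        for t in range(T - 1, -1, -1):
            xt, h_prev, r, z, rh, hc = self._cache[t]
            dh = dh_out[:, :, t] + dh_next
            dz = dh * (hc - h_prev)
            dhc = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dhc * (1.0 - hc * hc)
            g["W"] += da_h.T @ xt
            g["U"] += da_h.T @ rh
            drh = da_h @ p["U"]
            dr = drh * h_prev
            dh_prev += drh * r
            da_r = dr * r * (1.0 - r)
            g["W_r"] += da_r.T @ xt
            g["U_r"] += da_r.T @ h_prev
            dh_prev += da_r @ p["U_r"]
            da_z = dz * z * (1.0 - z)
            g["W_z"] += da_z.T @ xt
            g["U_z"] += da_z.T @ h_prev
            dh_prev += da_z @ p["U_z"]
            dx[:, :, t] = da_h @ p["W"] + da_r @ p["W_r"] + da_z @ p["W_z"]
            dh_next = dh_prev
        return dx


class BiGRU(Layer):
    """Bidirectional GRU whose output is the SUM of the two directions."""

    def __init__(self, in_dim, hidden, rng=None, dtype=np.float32):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.fwd = GRUDirection(in_dim, hidden, rng, dtype)
        self.bwd = GRUDirection(in_dim, hidden, rng, dtype)
        for name, arr in self.fwd.params.items():
            self.params[f"fwd.{name}"] = arr
        for name, arr in self.bwd.params.items():
            self.params[f"bwd.{name}"] = arr
        self.zero_grad()

    def zero_grad(self):
        self.fwd.zero_grad()
        self.bwd.zero_grad()
        for name in self.fwd.grads:
            self.grads[f"fwd.{name}"] = self.fwd.grads[name]
        for name in self.bwd.grads:
            self.grads[f"bwd.{name}"] = self.bwd.grads[name]

    def forward(self, x, training=False):
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, :, ::-1], training)[:, :, ::-1]
        return hf + hb

    def backward(self, dout):
        dx_f = self.fwd.backward(dout)
        dx_b = self.bwd.backward(dout[:, :, ::-1])[:, :, ::-1]
        return dx_f + dx_b


def global_average_context(h: np.ndarray) -> np.ndarray:
    """Per-channel mean over positions: (N, H, T) -> (N, H)  (or (H,T)->(H,))."""
    h = np.asarray(h)
    if h.shape[-1] < 1:
        raise ValueError("need at least one position")
    return h.mean(axis=-1)
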