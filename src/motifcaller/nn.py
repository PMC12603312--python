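"""Minimal numpy layer stack with hand-written backprop.

Implements exactly the pieces the caller network needs — 1-D convolution,
max-pooling, bidirectional GRU, linear — each as a layer object holding its
parameters and gradients, plus an Adam optimizer with global-norm gradient
clipping.  Sequences are batched as (B, T, C) arrays with an explicit
per-sample length so variable-length reads can share a padded batch; the
GRU applies the length mask on both passes, which matters for the reverse
direction (padding must not leak into valid frames).

Computation runs in float32 (the CTC lattice runs in float64 separately);
all gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "BatchNorm1d", "MaxPool1d", "BiGRU", "Linear", "Sequential", "Adam"]

DTYPE = np.float32


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Layer:
    """Base: params/grads are parallel dicts of numpy arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trained state (e.g. BN moments)

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def out_length(self, length: np.ndarray) -> np.ndarray:
        return length

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution with optional stride and ReLU.

    Weights are stored as (C_in * kernel, C_out) matching the im2col window
    layout (channel-major, tap-minor), so forward is a single matmul.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 5,
        stride: int = 1,
        relu: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.relu = kernel, stride, relu
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he(rng, (c_in * kernel, c_out), c_in * kernel)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.zero_grad()

    def out_length(self, length: np.ndarray) -> np.ndarray:
        return -(-length // self.stride)  # ceil division

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        k, s = self.k, self.stride
        left = k // 2
        xp = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, T, C, k)
        cols = np.ascontiguousarray(win[:, ::s])  # (B, T_out, C, k)
        self._cols = cols.reshape(B, -1, C * k)
        z = self._cols @ self.params["W"] + self.params["b"]
        self._z = z
        self._in_shape = (B, T, C)
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        k, s = self.k, self.stride
        dz = dy * (self._z > 0) if self.relu else dy
        dz = dz.astype(DTYPE, copy=False)
        self.grads["W"] += self._cols.reshape(-1, C * k).T @ dz.reshape(-1, self.c_out)
        self.grads["b"] += dz.sum(axis=(0, 1))
        dcols = (dz @ self.params["W"].T).reshape(B, -1, C, k)
        left = k // 2
        dxp = np.zeros((B, T + k - 1, C), dtype=DTYPE)
        t_idx = np.arange(dcols.shape[1]) * s
        for j in range(k):
            dxp[:, t_idx + j] += dcols[:, :, :, j]
        return dxp[:, left : left + T]


class MaxPool1d(Layer):
    """Non-overlapping temporal max pool (kernel == stride); remainder truncated."""

    def __init__(self, stride: int = 4) -> None:
        super().__init__()
        self.stride = stride

    def out_length(self, length: np.ndarray) -> np.ndarray:
        return length // self.stride

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        s = self.stride
        T_out = T // s
        xt = x[:, : T_out * s].reshape(B, T_out, s, C)
        self._arg = xt.argmax(axis=2)
        self._in_shape = (B, T, C)
        return np.take_along_axis(xt, self._arg[:, :, None], axis=2)[:, :, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        s = self.stride
        T_out = T // s
        dxt = np.zeros((B, T_out, s, C), dtype=DTYPE)
        np.put_along_axis(dxt, self._arg[:, :, None], dy[:, :, None].astype(DTYPE), axis=2)
        dx = np.zeros((B, T, C), dtype=DTYPE)
        dx[:, : T_out * s] = dxt.reshape(B, T_out * s, C)
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time), with optional ReLU.

    Training mode normalizes with batch statistics and tracks running
    moments; ``eval()`` switches to the running statistics for inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, relu: bool = True) -> None:
        super().__init__()
        self.relu = relu
        self.momentum = momentum
        self.eps = 1e-5
        self.training = True
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.buffers["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self.buffers["running_var"] = np.ones(channels, dtype=DTYPE)
        self.zero_grad()

    def eval(self) -> None:
        self.training = False

    def train(self) -> None:
        self.training = True

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.buffers["running_mean"][...] = (
                m * self.buffers["running_mean"] + (1 - m) * mean
            )
            self.buffers["running_var"][...] = (
                m * self.buffers["running_var"] + (1 - m) * var
            )
        else:
            mean, var = self.buffers["running_mean"], self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv = xhat, inv
        self._n = x.shape[0] * x.shape[1]
        z = self.params["gamma"] * xhat + self.params["beta"]
        self._z = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * (self._z > 0) if self.relu else dy
        dz = dz.astype(DTYPE, copy=False)
        xhat, inv, n = self._xhat, self._inv, self._n
        self.grads["gamma"] += (dz * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dz.sum(axis=(0, 1))
        dxhat = dz * self.params["gamma"]
        if self.training:
            dx = (
                dxhat
                - dxhat.mean(axis=(0, 1))
                - xhat * (dxhat * xhat).mean(axis=(0, 1))
            ) * inv
        else:
            dx = dxhat * inv
        return dx.astype(DTYPE, copy=False)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _GRUDirection:
    """One direction of a GRU layer; owns its parameter slices.

    Gate order along the 3H axis is (reset, update, candidate), with the
    candidate's recurrent term gated by reset before the tanh:
        r = sigma(x W_r + h U_r),  z = sigma(x W_z + h U_z),
        n = tanh(x W_n + r * (h U_n + b_n)),  h' = (1 - z) n + z h.
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator) -> None:
        H = hidden
        self.H = H
        scale_x = np.sqrt(1.0 / c_in)
        # orthogonal recurrent blocks keep the hidden dynamics well-conditioned
        Wh = np.concatenate([_orthogonal(rng, H) for _ in range(3)], axis=1)
        self.params = {
            "Wx": rng.uniform(-scale_x, scale_x, size=(c_in, 3 * H)).astype(DTYPE),
            "Wh": Wh.astype(DTYPE),
            "bx": np.zeros(3 * H, dtype=DTYPE),
            "bh": np.zeros(3 * H, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, mask: np.ndarray, reverse: bool) -> np.ndarray:
        """x: (B, T, C); mask: (B, T) in {0,1}.  Masked steps carry h through."""
        B, T, _ = x.shape
        H = self.H
        Wx, Wh, bx, bh = (self.params[k] for k in ("Wx", "Wh", "bx", "bh"))
        xp = x @ Wx + bx  # (B, T, 3H)
        h = np.zeros((B, H), dtype=DTYPE)
        hs = np.zeros((B, T, H), dtype=DTYPE)
        # caches for backward (per-step activations)
        self._hprev = np.zeros((B, T, H), dtype=DTYPE)
        self._r = np.zeros((B, T, H), dtype=DTYPE)
        self._z = np.zeros((B, T, H), dtype=DTYPE)
        self._n = np.zeros((B, T, H), dtype=DTYPE)
        self._hh_n = np.zeros((B, T, H), dtype=DTYPE)
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            hp = h @ Wh + bh  # (B, 3H)
            r = _sigmoid(xp[:, t, :H] + hp[:, :H])
            z = _sigmoid(xp[:, t, H : 2 * H] + hp[:, H : 2 * H])
            hh_n = hp[:, 2 * H :]
            n = np.tanh(xp[:, t, 2 * H :] + r * hh_n)
            m = mask[:, t : t + 1]
            self._hprev[:, t] = h
            self._r[:, t], self._z[:, t] = r, z
            self._n[:, t], self._hh_n[:, t] = n, hh_n
            h = m * ((1.0 - z) * n + z * h) + (1.0 - m) * h
            hs[:, t] = h
        self._x = x
        self._mask = mask
        self._reverse = reverse
        self._steps = list(steps)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        B, T, _ = self._x.shape
        H = self.H
        Wh = self.params["Wh"]
        dxp = np.zeros((B, T, 3 * H), dtype=DTYPE)
        dhp = np.zeros((B, T, 3 * H), dtype=DTYPE)
        dh = np.zeros((B, H), dtype=DTYPE)
        for t in reversed(self._steps):
            h_prev = self._hprev[:, t]
            r, z = self._r[:, t], self._z[:, t]
            n, hh_n = self._n[:, t], self._hh_n[:, t]
            m = self._mask[:, t : t + 1]
            dh_total = dh + dhs[:, t]
            dh_new = m * dh_total
            dh = (1.0 - m) * dh_total
            dz = dh_new * (h_prev - n)
            dn = dh_new * (1.0 - z)
            dh += dh_new * z
            dn_pre = dn * (1.0 - n * n)
            dhh_n = dn_pre * r
            dr_pre = (dn_pre * hh_n) * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            dxp[:, t, :H] = dr_pre
            dxp[:, t, H : 2 * H] = dz_pre
            dxp[:, t, 2 * H :] = dn_pre
            dhp[:, t, :H] = dr_pre
            dhp[:, t, H : 2 * H] = dz_pre
            dhp[:, t, 2 * H :] = dhh_n
            dh += dhp[:, t] @ Wh.T
        flat_hprev = self._hprev.reshape(-1, H)
        flat_dhp = dhp.reshape(-1, 3 * H)
        flat_x = self._x.reshape(-1, self._x.shape[2])
        flat_dxp = dxp.reshape(-1, 3 * H)
        self.grads["Wh"] += flat_hprev.T @ flat_dhp
        self.grads["bh"] += flat_dhp.sum(axis=0)
        self.grads["Wx"] += flat_x.T @ flat_dxp
        self.grads["bx"] += flat_dxp.sum(axis=0)
        return dxp @ self.params["Wx"].T


class BiGRU(Layer):
    """Bidirectional GRU layer; output concatenates both directions (2H)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.fwd = _GRUDirection(c_in, hidden, rng)
        self.bwd = _GRUDirection(c_in, hidden, rng)
        for tag, d in (("f", self.fwd), ("b", self.bwd)):
            for k, v in d.params.items():
                self.params[f"{tag}_{k}"] = v
        self.zero_grad()

    def zero_grad(self) -> None:
        super().zero_grad()
        # re-alias the direction grads onto the (fresh) layer grad buffers
        for tag, d in (("f", self.fwd), ("b", self.bwd)):
            for k in d.params:
                d.grads[k] = self.grads[f"{tag}_{k}"]

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(DTYPE)
        hf = self.fwd.forward(x, mask, reverse=False)
        hb = self.bwd.forward(x, mask, reverse=True)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.hidden
        dy = dy.astype(DTYPE, copy=False)
        return self.fwd.backward(dy[:, :, :H]) + self.bwd.backward(dy[:, :, H:])


class Linear(Layer):
    def __init__(
        self, c_in: int, c_out: int, relu: bool = False, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.relu = relu
        self.params["W"] = _he(rng, (c_in, c_out), c_in)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._z = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * (self._z > 0) if self.relu else dy
        dz = dz.astype(DTYPE, copy=False)
        c_in = self._x.shape[-1]
        self.grads["W"] += self._x.reshape(-1, c_in).T @ dz.reshape(-1, dz.shape[-1])
        self.grads["b"] += dz.reshape(-1, dz.shape[-1]).sum(axis=0)
        return dz @ self.params["W"].T


class Sequential:
    """Layer pipeline tracking per-sample lengths through strided stages."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def out_length(self, lengths: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            lengths = layer.out_length(lengths)
        return lengths

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = x.astype(DTYPE, copy=False)
        for layer in self.layers:
            x = layer.forward(x, lengths)
            lengths = layer.out_length(lengths)
        return x, lengths

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(DTYPE, copy=False)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                out.append((f"layer{i}.{k}", layer.params[k], layer.grads[k]))
        return out

    def train(self) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = True

    def eval(self) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = False

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.copy() for name, p, _ in self.named_params()}
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers.items():
                out[f"layer{i}.buf.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.named_params():
            if name not in state:
                raise KeyError(f"missing parameter {name} in checkpoint")
            if state[name].shape != p.shape:
                raise ValueError(f"shape mismatch for {name}")
            p[...] = state[name].astype(DTYPE)
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers.items():
                key = f"layer{i}.buf.{k}"
                if key in state:
                    v[...] = state[key].astype(DTYPE)


class Adam:
    """Adam with global-norm gradient clipping and linear step warmup."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float = 5.0,
        warmup_steps: int = 100,
    ) -> None:
        self.model = model
        self.lr, self.betas, self.eps, self.clip_norm = lr, betas, eps, clip_norm
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in model.named_params()}
        self.v = {name: np.zeros_like(p) for name, p, _ in model.named_params()}

    def step(self) -> float:
        """Apply one update; returns the (pre-clip) global gradient norm."""
        named = self.model.named_params()
        norm = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for _, _, g in named)))
        scale = DTYPE(1.0)
        if self.clip_norm and norm > self.clip_norm:
            scale = DTYPE(self.clip_norm / (norm + 1e-12))
        self.t += 1
        b1, b2 = self.betas
        lr_t = self.lr * min(1.0, self.t / max(self.warmup_steps, 1))
        for name, p, g in named:
            g = g * scale
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p -= (lr_t * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
        return norm
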