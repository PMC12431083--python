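"""Minimal NumPy layer engine for 1-D convolutional networks.

Implements exactly the layer set the classifier needs — same-padded Conv1D
(stride 1) via im2col GEMM, the CBAM-style channel-attention gate, "same"
average pooling (pool 3, stride 2, edge windows average in-bounds samples
only), global average pooling, dense layers and a softmax/cross-entropy head —
each with an explicit backward pass.  All computation is float32.

Array convention: batches are ``(B, L, C)`` — batch, temporal length,
channels.  Each layer caches what its backward pass needs; ``backward``
accumulates parameter gradients in ``layer.grads`` and returns the gradient
with respect to its input.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter-free unless overridden."""

    name = "layer"

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def output_shape(self, L: int, C: int) -> tuple[int, int]:
        return L, C


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1, optional ReLU.

    Weights ``W`` have shape (k, C_in, C_out); bias ``b`` shape (C_out,).
    Parameter count = k·C_in·C_out + C_out.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, *, relu: bool = True,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.relu = relu
        self.name = name
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (kernel * c_in + kernel * c_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(kernel, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return self._grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        k = self.kernel
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (B, L, k, C_in): window j of length k starting at each output position
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        self._cols = cols.reshape(B * L, k * self.c_in)
        Wm = self.W.transpose(0, 1, 2).reshape(k * self.c_in, self.c_out)
        y = self._cols @ Wm + self.b
        y = y.reshape(B, L, self.c_out)
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        self._in_shape = (B, L)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L = self._in_shape
        k, ci, co = self.kernel, self.c_in, self.c_out
        if self.relu:
            dout = np.where(self._mask, dout, 0.0)
        dflat = dout.reshape(B * L, co)
        self._grads["W"][...] = (self._cols.T @ dflat).reshape(k, ci, co)
        self._grads["b"][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(k * ci, co).T).reshape(B, L, k, ci)
        pad = (k - 1) // 2
        dxp = np.zeros((B, L + 2 * pad, ci), dtype=DTYPE)
        for j in range(k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, pad : pad + L, :]


class ChannelAttention(Layer):
    """CBAM-style channel gate: shared bias-free bottleneck MLP over the
    per-channel temporal mean and max, summed before the sigmoid, multiplied
    back onto the feature map.  ``W0`` is (C/r, C), ``W1`` is (C, C/r);
    parameter count = 2·C·(C/r)."""

    def __init__(self, channels: int, reduction: int = 8, *,
                 rng: np.random.Generator | None = None, name: str = "attn"):
        hidden = channels // reduction  # floor, as in a Keras Dense(C // r)
        if hidden < 1:
            raise ValueError(
                f"reduction ratio {reduction} leaves no hidden units for "
                f"{channels} channels"
            )
        self.channels, self.reduction = channels, reduction
        self.name = name
        rng = rng or np.random.default_rng()
        l0 = np.sqrt(6.0 / (channels + hidden))
        l1 = np.sqrt(6.0 / (hidden + channels))
        self.W0 = rng.uniform(-l0, l0, size=(hidden, channels)).astype(DTYPE)
        self.W1 = rng.uniform(-l1, l1, size=(channels, hidden)).astype(DTYPE)
        self._grads = {"W0": np.zeros_like(self.W0), "W1": np.zeros_like(self.W1)}
        self.last_attention: np.ndarray | None = None  # (B, C), for introspection

    @property
    def params(self):
        return {"W0": self.W0, "W1": self.W1}

    @property
    def grads(self):
        return self._grads

    def attention(self, x: np.ndarray) -> np.ndarray:
        """The gate vector A ∈ (0,1)^C for each item of the batch."""
        d_avg = x.mean(axis=1)
        d_max = x.max(axis=1)
        h_avg = np.maximum(d_avg @ self.W0.T, 0.0)
        h_max = np.maximum(d_max @ self.W0.T, 0.0)
        return sigmoid((h_avg + h_max) @ self.W1.T)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        self._x = x
        self._d_avg = x.mean(axis=1)
        self._argmax = x.argmax(axis=1)  # (B, C)
        d_max = np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]
        self._d_max = d_max
        self._z_avg = self._d_avg @ self.W0.T
        self._z_max = d_max @ self.W0.T
        h = np.maximum(self._z_avg, 0.0) + np.maximum(self._z_max, 0.0)
        self._h = h
        A = sigmoid(h @ self.W1.T)
        self._A = A
        self.last_attention = A
        return x * A[:, None, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, A = self._x, self._A
        B, L, C = x.shape
        dx = dout * A[:, None, :]
        dA = np.einsum("blc,blc->bc", dout, x)
        ds = dA * A * (1.0 - A)                      # pre-sigmoid grad (B, C)
        self._grads["W1"][...] = ds.T @ self._h
        dh = ds @ self.W1                            # (B, hidden)
        dz_avg = dh * (self._z_avg > 0)
        dz_max = dh * (self._z_max > 0)
        self._grads["W0"][...] = dz_avg.T @ self._d_avg + dz_max.T @ self._d_max
        dd_avg = dz_avg @ self.W0                    # (B, C)
        dd_max = dz_max @ self.W0
        dx += dd_avg[:, None, :] / L
        np.put_along_axis(
            dx, self._argmax[:, None, :],
            np.take_along_axis(dx, self._argmax[:, None, :], axis=1)
            + dd_max[:, None, :],
            axis=1,
        )
        return dx


def pool_output_length(L: int, stride: int = 2) -> int:
    """'Same' pooling output length: ceil(L / stride)."""
    return -(-L // stride)


class AvgPool1D(Layer):
    """Average pooling, pool 3, stride 2, 'same' padding.

    Output length is ceil(L/2); edge windows average only the in-bounds
    samples (no zero contribution from implicit padding).
    """

    pool = 3
    stride = 2

    def __init__(self, name: str = "avgpool"):
        self.name = name

    def output_shape(self, L: int, C: int) -> tuple[int, int]:
        return pool_output_length(L, self.stride), C

    def _geometry(self, L: int):
        out = pool_output_length(L, self.stride)
        total_pad = max((out - 1) * self.stride + self.pool - L, 0)
        left = total_pad // 2
        starts = np.arange(out) * self.stride - left
        lo = np.clip(starts, 0, L)
        hi = np.clip(starts + self.pool, 0, L)
        return out, starts, lo, hi, (hi - lo).astype(DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        out, starts, lo, hi, counts = self._geometry(L)
        cs = np.concatenate(
            [np.zeros((B, 1, C), dtype=np.float64), np.cumsum(x, axis=1, dtype=np.float64)],
            axis=1,
        )
        y = (cs[:, hi, :] - cs[:, lo, :]) / counts[None, :, None]
        self._cache = (L, starts, lo, hi, counts)
        return y.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        L, starts, lo, hi, counts = self._cache
        B, out, C = dout.shape
        d = dout / counts[None, :, None]
        dx = np.zeros((B, L, C), dtype=DTYPE)
        for j in range(self.pool):
            pos = starts + j
            valid = (pos >= 0) & (pos < L)
            dx[:, pos[valid], :] += d[:, valid, :]
        return dx


class GlobalAvgPool(Layer):
    """Mean over the temporal axis: (B, L, C) -> (B, C)."""

    def __init__(self, name: str = "gap"):
        self.name = name

    def output_shape(self, L: int, C: int) -> tuple[int, int]:
        return 1, C

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C = dout.shape
        return np.repeat(dout[:, None, :] / self._L, self._L, axis=1)


class Dense(Layer):
    """Fully connected layer, optional ReLU.  Parameters: in·out + out."""

    def __init__(self, n_in: int, n_out: int, *, relu: bool = False,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        self.n_in, self.n_out, self.relu = n_in, n_out, relu
        self.name = name
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self._grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return self._grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = np.where(self._mask, dout, 0.0)
        self._grads["W"][...] = self._x.T @ dout
        self._grads["b"][...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy over the batch."""
    return float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())


class Adam:
    """Adam optimizer over a list of layers (default TensorFlow settings)."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] += (1.0 - self.beta1) * (g - m[k])
                v[k] += (1.0 - self.beta2) * (g * g - v[k])
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
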