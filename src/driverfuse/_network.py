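"""Minimal 1-D convolutional network on numpy.

The network treats the 2 x L' encoded mutation-pair matrix as a length-L'
sequence with 2 channels (reference row, mutated row).  Architecture:
1-3 conv layers (ReLU), global max pooling over positions, 1-3 dense layers
(ReLU, inverted dropout), and a single sigmoid output unit trained with
binary cross-entropy and Adam.  The first convolution uses a kernel of
``kernel_symbols`` symbols and a stride of one symbol block, so block
encodings (one-hot, embedding) stay aligned to symbol boundaries; deeper
convolutions use kernel 3, stride 1.

Everything is seeded through numpy Generators, so training is bit-for-bit
reproducible for a fixed seed, data and architecture.
"""

from __future__ import annotations

import numpy as np


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(B, C, L) -> (B, T, C*kernel) window matrix."""
    B, C, L = x.shape
    T = (L - kernel) // stride + 1
    idx = stride * np.arange(T)[:, None] + np.arange(kernel)[None, :]  # (T, K)
    cols = x[:, :, idx]                      # (B, C, T, K)
    return cols.transpose(0, 2, 1, 3).reshape(B, T, C * kernel)


class _Adam:
    def __init__(self, shape, lr: float):
        self.lr = lr
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, w: np.ndarray, g: np.ndarray) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        mh = self.m / (1 - b1**self.t)
        vh = self.v / (1 - b2**self.t)
        w -= self.lr * mh / (np.sqrt(vh) + eps)


class SmallCNN:
    """Sequence CNN for binary driver/passenger classification."""

    def __init__(
        self,
        conv_filters: tuple[int, ...],
        dense_widths: tuple[int, ...],
        input_len: int,
        in_channels: int = 2,
        block: int = 1,
        kernel_symbols: int = 3,
        dropout: float = 0.25,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.dropout = float(dropout)
        self.rng = np.random.default_rng(seed)
        self.conv: list[dict] = []
        self.dense: list[dict] = []

        L, C = input_len, in_channels
        for i, f in enumerate(conv_filters):
            if i == 0:
                kernel = min(kernel_symbols * block, L)
                stride = block
            else:
                kernel = min(3, L)
                stride = 1
            T = (L - kernel) // stride + 1
            if T < 1:
                raise ValueError(f"conv layer {i}: input length {L} shorter than kernel {kernel}")
            fan_in = C * kernel
            W = self.rng.normal(scale=np.sqrt(2.0 / fan_in), size=(f, fan_in))
            self.conv.append({"W": W, "b": np.zeros(f), "kernel": kernel, "stride": stride,
                              "opt_W": _Adam(W.shape, learning_rate), "opt_b": _Adam((f,), learning_rate)})
            L, C = T, f

        width_in = C
        for w in dense_widths:
            W = self.rng.normal(scale=np.sqrt(2.0 / width_in), size=(w, width_in))
            self.dense.append({"W": W, "b": np.zeros(w),
                               "opt_W": _Adam(W.shape, learning_rate), "opt_b": _Adam((w,), learning_rate)})
            width_in = w
        W = self.rng.normal(scale=np.sqrt(2.0 / width_in), size=(1, width_in))
        self.head = {"W": W, "b": np.zeros(1),
                     "opt_W": _Adam(W.shape, learning_rate), "opt_b": _Adam((1,), learning_rate)}

    # ------------------------------------------------------------------ forward

    def _forward(self, X: np.ndarray, train: bool = False):
        cache: dict = {"conv": [], "dense": [], "masks": []}
        a = X
        for layer in self.conv:
            cols = _im2col(a, layer["kernel"], layer["stride"])       # (B, T, CK)
            z = cols @ layer["W"].T + layer["b"]                      # (B, T, F)
            h = _relu(z)
            cache["conv"].append({"cols": cols, "z": z, "in_shape": a.shape})
            a = h.transpose(0, 2, 1)                                  # (B, F, T)
        # global max pool over positions
        pool_arg = a.argmax(axis=2)
        pooled = a.max(axis=2)                                        # (B, F)
        cache["pool_arg"] = pool_arg
        cache["pool_in_shape"] = a.shape
        h = pooled
        for layer in self.dense:
            z = h @ layer["W"].T + layer["b"]
            hh = _relu(z)
            if train and self.dropout > 0:
                mask = (self.rng.random(hh.shape) >= self.dropout) / (1.0 - self.dropout)
                hh = hh * mask
            else:
                mask = None
            cache["dense"].append({"in": h, "z": z})
            cache["masks"].append(mask)
            h = hh
        cache["head_in"] = h
        logit = h @ self.head["W"].T + self.head["b"]                 # (B, 1)
        cache["p"] = _sigmoid(logit).ravel()
        return cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64), train=False)["p"]

    def param_count(self) -> int:
        n = self.head["W"].size + self.head["b"].size
        for layer in self.conv + self.dense:
            n += layer["W"].size + layer["b"].size
        return int(n)

    # ----------------------------------------------------------------- backward

    def _backward(self, cache: dict, y: np.ndarray) -> dict:
        B = y.size
        grads: dict = {"conv": [], "dense": []}
        d = ((cache["p"] - y) / B)[:, None]                           # dL/dlogit, (B,1)
        grads["head"] = {"W": d.T @ cache["head_in"], "b": d.sum(axis=0)}
        dh = d @ self.head["W"]                                       # (B, width)
        for layer, lc, mask in zip(reversed(self.dense), reversed(cache["dense"]), reversed(cache["masks"])):
            if mask is not None:
                dh = dh * mask
            dz = dh * (lc["z"] > 0)
            grads["dense"].append({"W": dz.T @ lc["in"], "b": dz.sum(axis=0)})
            dh = dz @ layer["W"]
        grads["dense"].reverse()

        # unpool: route gradient to argmax positions
        Bsz, F, T = cache["pool_in_shape"]
        da = np.zeros((Bsz, F, T))
        bi = np.arange(Bsz)[:, None]
        fi = np.arange(F)[None, :]
        da[bi, fi, cache["pool_arg"]] = dh

        for layer, lc in zip(reversed(self.conv), reversed(cache["conv"])):
            dh_conv = da.transpose(0, 2, 1)                           # (B, T, F)
            dz = dh_conv * (lc["z"] > 0)
            grads["conv"].append({"W": np.einsum("btf,btk->fk", dz, lc["cols"]),
                                  "b": dz.sum(axis=(0, 1))})
            dcols = dz @ layer["W"]                                   # (B, T, CK)
            Bs, C, L = lc["in_shape"]
            K, S = layer["kernel"], layer["stride"]
            dx = np.zeros((Bs, C, L))
            dcols4 = dcols.reshape(Bs, -1, C, K)
            for t in range(dcols4.shape[1]):
                dx[:, :, t * S : t * S + K] += dcols4[:, t]
            da = dx
        grads["conv"].reverse()
        return grads

    def train_epoch(self, X: np.ndarray, y: np.ndarray, batch_size: int = 32) -> float:
        """One pass over the data in shuffled minibatches; returns mean BCE."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        order = self.rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), batch_size):
            idx = order[start : start + batch_size]
            cache = self._forward(X[idx], train=True)
            p = np.clip(cache["p"], 1e-12, 1 - 1e-12)
            losses.append(float(-np.mean(y[idx] * np.log(p) + (1 - y[idx]) * np.log(1 - p))))
            grads = self._backward(cache, y[idx])
            for layer, g in zip(self.conv, grads["conv"]):
                layer["opt_W"].step(layer["W"], g["W"])
                layer["opt_b"].step(layer["b"], g["b"])
            for layer, g in zip(self.dense, grads["dense"]):
                layer["opt_W"].step(layer["W"], g["W"])
                layer["opt_b"].step(layer["b"], g["b"])
            self.head["opt_W"].step(self.head["W"], grads["head"]["W"])
            self.head["opt_b"].step(self.head["b"], grads["head"]["b"])
        return float(np.mean(losses))
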