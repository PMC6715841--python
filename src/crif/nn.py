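"""Minimal numpy implementation of the 4-layer hyperspectrum CNN.

The network takes a 6 x 32 hyperspectrum matrix as a one-channel image
and applies two 3x3 convolutional layers (replicate padding, ReLU, no
pooling — the input is tiny) followed by two linear layers.  Training
is Adam on softmax cross-entropy, one gradient step per minibatch.
Everything is plain numpy so results are exactly reproducible from a
seed on any machine.
"""

from __future__ import annotations

import numpy as np

H, W = 6, 32  # hyperspectrum geometry


def _pad_replicate(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")


def _unpad_replicate_grad(dxp: np.ndarray) -> np.ndarray:
    """Backward of replicate padding: fold border gradients onto edge pixels."""
    dx = dxp[:, :, 1:-1, 1:-1].copy()
    dx[:, :, 0, :] += dxp[:, :, 0, 1:-1]
    dx[:, :, -1, :] += dxp[:, :, -1, 1:-1]
    dx[:, :, :, 0] += dxp[:, :, 1:-1, 0]
    dx[:, :, :, -1] += dxp[:, :, 1:-1, -1]
    dx[:, :, 0, 0] += dxp[:, :, 0, 0]
    dx[:, :, 0, -1] += dxp[:, :, 0, -1]
    dx[:, :, -1, 0] += dxp[:, :, -1, 0]
    dx[:, :, -1, -1] += dxp[:, :, -1, -1]
    return dx


class _Conv3x3:
    """3x3 convolution, stride 1, replicate padding (output same size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = _pad_replicate(x)
        cols = np.empty((n, c * 9, h * w))
        k = 0
        for dy in range(3):
            for dx in range(3):
                cols[:, k * c:(k + 1) * c, :] = xp[:, :, dy:dy + h, dx:dx + w].reshape(n, c, -1)
                k += 1
        # weights in the same (offset, channel) order as cols
        wf = np.stack(
            [self.w[:, :, dy, dx] for dy in range(3) for dx in range(3)], axis=1
        ).reshape(self.w.shape[0], -1)  # (c_out, 9*c) with blocks [offset][channel]
        out = np.matmul(wf, cols) + self.b[None, :, None]
        self._cache = (x.shape, cols, wf)
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray):
        (n, c, h, w), cols, wf = self._cache
        doutf = dout.reshape(n, -1, h * w)
        dwf = np.matmul(doutf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = doutf.sum(axis=(0, 2))
        dw = np.zeros_like(self.w)
        k = 0
        for dy in range(3):
            for dx in range(3):
                dw[:, :, dy, dx] = dwf[:, k * c:(k + 1) * c]
                k += 1
        self.dw = dw
        dcols = np.matmul(wf.T, doutf)
        dxp = np.zeros((n, c, h + 2, w + 2))
        k = 0
        for dy in range(3):
            for dx in range(3):
                dxp[:, :, dy:dy + h, dx:dx + w] += dcols[:, k * c:(k + 1) * c, :].reshape(n, c, h, w)
                k += 1
        return _unpad_replicate_grad(dxp)

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class SmallCNN:
    """conv(8) -> ReLU -> conv(16) -> ReLU -> linear(64) -> ReLU -> linear(K)."""

    def __init__(
        self,
        n_classes: int,
        seed: int = 0,
        conv1_filters: int = 8,
        conv2_filters: int = 16,
        hidden_units: int = 64,
        lr: float = 1e-3,
        batch_size: int = 10,
    ):
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv3x3(1, conv1_filters, rng)
        self.conv2 = _Conv3x3(conv1_filters, conv2_filters, rng)
        self.fc1 = _Linear(conv2_filters * H * W, hidden_units, rng)
        self.fc2 = _Linear(hidden_units, n_classes, rng)
        self.n_classes = n_classes
        self.lr = lr
        self.batch_size = batch_size
        self._rng = rng
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # ---- forward/backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0.0)
        a2 = self.conv2.forward(r1)
        r2 = np.maximum(a2, 0.0)
        flat = r2.reshape(len(x), -1)
        h1 = self.fc1.forward(flat)
        rh = np.maximum(h1, 0.0)
        logits = self.fc2.forward(rh)
        if train:
            self._acts = (a1, a2, r2.shape, h1)
        return logits

    def _backward(self, dlogits: np.ndarray) -> None:
        a1, a2, r2_shape, h1 = self._acts
        drh = self.fc2.backward(dlogits)
        dh1 = drh * (h1 > 0)
        dflat = self.fc1.backward(dh1)
        dr2 = dflat.reshape(r2_shape)
        da2 = dr2 * (a2 > 0)
        dr1 = self.conv2.backward(da2)
        da1 = dr1 * (a1 > 0)
        self.conv1.backward(da1)

    def _layers(self):
        return (self.conv1, self.conv2, self.fc1, self.fc2)

    def _adam_step(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self._layers():
            for p, g in layer.params_and_grads():
                if i not in self._adam_state:
                    self._adam_state[i] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._adam_state[i]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * (g * g)
                step = m / ((1 - beta1**t) * (np.sqrt(v / (1 - beta2**t)) + eps))
                step *= self.lr
                p -= step
                i += 1

    # ---- public API -------------------------------------------------------

    def fit(
        self,
        matrices: np.ndarray,  # (n, 6, 32)
        y: np.ndarray,  # integer class indices
        epochs: int = 100,
        steps_per_epoch: int = 100,
    ) -> "SmallCNN":
        """Train for ``epochs`` x ``steps_per_epoch`` minibatch gradient steps.

        Minibatches are drawn with replacement so training sets smaller
        than steps x batch size still follow the schedule.
        """
        x = np.asarray(matrices, dtype=float).reshape(-1, 1, H, W)
        y = np.asarray(y, dtype=int)
        n = len(x)
        for _ in range(epochs):
            for _ in range(steps_per_epoch):
                idx = self._rng.integers(0, n, size=min(self.batch_size, n))
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb, train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                dlogits = p.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self._backward(dlogits)
                self._adam_step()
        return self

    def predict_scores(self, matrices: np.ndarray) -> np.ndarray:
        x = np.asarray(matrices, dtype=float).reshape(-1, 1, H, W)
        return self._forward(x, train=False)

    def predict(self, matrices: np.ndarray) -> np.ndarray:
        """Class indices; argmax ties break toward the lower index."""
        return np.argmax(self.predict_scores(matrices), axis=1)
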