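"""A small from-scratch convolutional image classifier in NumPy.

``TinyScalogramCNN`` is the desk-scale backbone of the image branch: a
14x14 average-pool stem taking 224x224x3 scalogram images down to
16x16x3, a per-pixel standardisation layer fitted on the training set
(cheap conditioning in place of batch normalisation), three 3x3 conv
blocks (8, 16, 32 filters; ReLU; the first two followed by 2x2 max
pooling), global average pooling and a softmax head.
It trains from scratch with plain minibatch SGD (momentum, cross-entropy
loss) and is exactly reproducible from its seed. Convolutions use
im2col + matmul; the backward convolution reuses the forward path with a
spatially flipped, channel-transposed kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_same(X: np.ndarray, W: np.ndarray, b: np.ndarray | None):
    """3x3 'same' convolution. X: (N,H,W,C); W: (3,3,C,F) -> (N,H,W,F)."""
    N, H, Wd, C = X.shape
    F = W.shape[-1]
    Xp = np.pad(X, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(Xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    cols = cols.reshape(N * H * Wd, C * 9)
    Wm = W.transpose(2, 0, 1, 3).reshape(C * 9, F)
    out = cols @ Wm
    if b is not None:
        out += b
    return out.reshape(N, H, Wd, F), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray):
    """Gradients of a 3x3 'same' conv. Returns dX, dW, db."""
    N, H, Wd, F = dout.shape
    C = W.shape[2]
    dflat = dout.reshape(N * H * Wd, F)
    dWm = cols.T @ dflat
    dW = dWm.reshape(C, 3, 3, F).transpose(1, 2, 0, 3)
    db = dflat.sum(axis=0)
    # dX = conv(dout, W flipped spatially, channels transposed)
    W_flip = W[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,F,C)
    dX, _ = _conv_same(dout, np.ascontiguousarray(W_flip), None)
    return dX, dW, db


def _maxpool2(X: np.ndarray):
    N, H, W, C = X.shape
    win = X.reshape(N, H // 2, 2, W // 2, 2, C)
    out = win.max(axis=(2, 4))
    mask = win == out[:, :, None, :, None, :]
    # distribute gradient evenly across ties
    mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
    return out, mask


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray):
    N, Hh, W2, C = dout.shape
    d = dout[:, :, None, :, None, :] * mask
    return d.reshape(N, Hh * 2, W2 * 2, C)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TinyScalogramCNN:
    """3-conv-block softmax image classifier (~6k parameters)."""

    STEM_POOL = 14  # 224 / 14 = 16
    CHANNELS = (8, 16, 32)

    def __init__(self, n_classes: int = 2, seed: int = 0):
        self.n_classes = n_classes
        self.seed = seed
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.CHANNELS
        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "W1": he((3, 3, 3, c1), 27), "b1": np.zeros(c1),
            "W2": he((3, 3, c1, c2), 9 * c1), "b2": np.zeros(c2),
            "W3": he((3, 3, c2, c3), 9 * c2), "b3": np.zeros(c3),
            "Wf": he((c3, n_classes), c3), "bf": np.zeros(n_classes),
        }
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        # per-pixel input standardisation, fitted on the training set
        self._norm_mu: np.ndarray | None = None
        self._norm_sd: np.ndarray | None = None

    # -- data plumbing -------------------------------------------------

    @staticmethod
    def preprocess(images: np.ndarray) -> np.ndarray:
        """224x224x3 uint8 images -> pooled, centred float32 (N,16,16,3)."""
        X = np.asarray(images)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1:] == (16, 16, 3):
            return X.astype(np.float32)
        if X.shape[1:] != (224, 224, 3):
            raise ValueError(f"expected (N,224,224,3) images; got {X.shape}")
        p = TinyScalogramCNN.STEM_POOL
        X = X.reshape(X.shape[0], 16, p, 16, p, 3).mean(axis=(2, 4))
        return (X / 255.0 - 0.5).astype(np.float32)

    def _normalise(self, X: np.ndarray) -> np.ndarray:
        if self._norm_mu is None:
            return X
        return (X - self._norm_mu) / self._norm_sd

    # -- forward / backward --------------------------------------------

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        P = self.params
        a1, cols1 = _conv_same(X, P["W1"], P["b1"])
        r1 = np.maximum(a1, 0)
        p1, m1 = _maxpool2(r1)  # 8x8
        a2, cols2 = _conv_same(p1, P["W2"], P["b2"])
        r2 = np.maximum(a2, 0)
        p2, m2 = _maxpool2(r2)  # 4x4
        a3, cols3 = _conv_same(p2, P["W3"], P["b3"])
        r3 = np.maximum(a3, 0)
        gap = r3.mean(axis=(1, 2))
        logits = gap @ P["Wf"] + P["bf"]
        probs = _softmax(logits)
        cache = (X, a1, cols1, m1, p1, a2, cols2, m2, p2, a3, cols3, r3, gap) if keep_cache else None
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache):
        X, a1, cols1, m1, p1, a2, cols2, m2, p2, a3, cols3, r3, gap = cache
        P = self.params
        N = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N
        grads = {}
        grads["Wf"] = gap.T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dgap = dlogits @ P["Wf"].T
        H3 = r3.shape[1]
        dr3 = np.broadcast_to(dgap[:, None, None, :], r3.shape) / (H3 * H3)
        da3 = dr3 * (a3 > 0)
        dp2, grads["W3"], grads["b3"] = _conv_backward(da3, cols3, P["W3"])
        dr2 = _maxpool2_backward(dp2, m2)
        da2 = dr2 * (a2 > 0)
        dp1, grads["W2"], grads["b2"] = _conv_backward(da2, cols2, P["W2"])
        dr1 = _maxpool2_backward(dp1, m1)
        da1 = dr1 * (a1 > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(da1, cols1, P["W1"])
        return grads

    # -- public API ----------------------------------------------------

    def predict_proba(self, images: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        X = self._normalise(self.preprocess(images))
        out = []
        for i in range(0, len(X), batch_size):
            probs, _ = self._forward(X[i : i + batch_size])
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def save(self, path) -> None:
        """Checkpoint as .npz with a JSON config sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = dict(self.params)
        if self._norm_mu is not None:
            arrays["norm_mu"] = self._norm_mu
            arrays["norm_sd"] = self._norm_sd
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(
            json.dumps({"backbone": "tiny_test_cnn", "n_classes": self.n_classes,
                        "seed": self.seed, "channels": list(self.CHANNELS)}))

    @classmethod
    def load(cls, path) -> "TinyScalogramCNN":
        import json
        from pathlib import Path

        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        model = cls(n_classes=cfg["n_classes"], seed=cfg["seed"])
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for k in model.params:
            model.params[k] = data[k]
        if "norm_mu" in data:
            model._norm_mu = data["norm_mu"]
            model._norm_sd = data["norm_sd"]
        return model

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 10,
        learning_rate: float = 0.005,
        momentum: float = 0.9,
        n_minibatches: int = 10,
        seed: int | None = None,
    ) -> list[float]:
        """Minibatch SGD; returns the per-epoch mean cross-entropy trace."""
        X = self.preprocess(images)
        y = np.asarray(labels, dtype=np.intp)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least two classes")
        if epochs < 0:
            raise ValueError("epochs must be non-negative")
        if epochs > 0:
            # fit the input-standardisation layer on training data only
            self._norm_mu = X.mean(axis=0)
            self._norm_sd = X.std(axis=0).astype(np.float32) + np.float32(1e-4)
        X = self._normalise(X)
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        n = len(X)
        batch = max(1, int(np.ceil(n / n_minibatches)))
        trace: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch):
                idx = order[i : i + batch]
                Xb, yb = X[idx], y[idx]
                probs, cache = self._forward(Xb, keep_cache=True)
                losses.append(float(-np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, 1)).mean()))
                grads = self._backward(probs, yb, cache)
                for k, g in grads.items():
                    v = self._velocity[k]
                    v *= momentum
                    v -= learning_rate * g
                    self.params[k] += v
            trace.append(float(np.mean(losses)))
        return trace
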