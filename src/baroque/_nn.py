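"""Minimal feed-forward networks in numpy.

Two architectures back the package: a one-hidden-layer action-value
network (2N inputs -> hid_num ReLU -> 2 linear outputs) used by the
deep-Q local search, and a small 1-D convnet classifier (two conv/ReLU/
max-pool blocks, then fully-connected layers) used as an optional mask
evaluator.  Both train with Adam; gradients are hand-derived.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "QNetwork", "SmallConvNet"]


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class QNetwork:
    """Action-value network: input -> hidden ReLU -> 2 linear outputs."""

    def __init__(self, n_inputs: int, hidden: int = 64, lr: float = 1e-3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.n_inputs, self.hidden = n_inputs, hidden
        self.W1 = _he(rng, (n_inputs, hidden), n_inputs)
        self.b1 = np.zeros(hidden)
        self.W2 = _he(rng, (hidden, 2), hidden)
        self.b2 = np.zeros(2)
        self.opt = Adam(lr=lr)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def q_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = np.maximum(x @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2

    def train_step(self, states: np.ndarray, actions: np.ndarray,
                   targets: np.ndarray) -> float:
        """One Adam step on mean squared error of the taken-action values."""
        x = np.atleast_2d(np.asarray(states, dtype=float))
        a = np.asarray(actions, dtype=int)
        y = np.asarray(targets, dtype=float)
        n = x.shape[0]
        z1 = x @ self.W1 + self.b1
        h = np.maximum(z1, 0.0)
        q = h @ self.W2 + self.b2
        picked = q[np.arange(n), a]
        err = picked - y
        loss = float(np.mean(err**2))
        gq = np.zeros_like(q)
        gq[np.arange(n), a] = 2.0 * err / n
        gW2 = h.T @ gq
        gb2 = gq.sum(axis=0)
        gh = gq @ self.W2.T
        gz1 = gh * (z1 > 0)
        gW1 = x.T @ gz1
        gb1 = gz1.sum(axis=0)
        self.opt.step(self.params, [gW1, gb1, gW2, gb2])
        return loss

    def copy_from(self, other: "QNetwork") -> None:
        for p, q in zip(self.params, other.params):
            p[...] = q

    def clone(self) -> "QNetwork":
        twin = QNetwork(self.n_inputs, self.hidden, lr=self.opt.lr,
                        rng=np.random.default_rng(0))
        twin.copy_from(self)
        return twin


def _conv1d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (B,Cin,L), W (Cout,Cin,K) -> (B,Cout,L) with 'same' padding."""
    K = W.shape[2]
    pl, pr = (K - 1) // 2, K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    out = np.einsum("bilk,oik->bol", win, W) + b[None, :, None]
    return out, (xp, win, pl)


def _conv1d_same_backward(g: np.ndarray, W: np.ndarray, cache, L: int):
    xp, win, pl = cache
    gW = np.einsum("bilk,bol->oik", win, g)
    gb = g.sum(axis=(0, 2))
    gxp = np.zeros_like(xp)
    for k in range(W.shape[2]):
        gxp[:, :, k : k + L] += np.einsum("bol,oi->bil", g, W[:, :, k])
    return gxp[:, :, pl : pl + L], gW, gb


def _maxpool2(x: np.ndarray):
    """Kernel 2, stride 2, floor truncation. x (B,C,L) -> (B,C,L//2)."""
    B, C, L = x.shape
    L2 = L // 2
    xr = x[:, :, : 2 * L2].reshape(B, C, L2, 2)
    idx = xr.argmax(axis=-1)
    return xr.max(axis=-1), (idx, L)


def _maxpool2_backward(g: np.ndarray, cache):
    idx, L = cache
    B, C, L2 = g.shape
    gx = np.zeros((B, C, L))
    flat = np.zeros((B, C, L2, 2))
    np.put_along_axis(flat, idx[..., None], g[..., None], axis=-1)
    gx[:, :, : 2 * L2] = flat.reshape(B, C, 2 * L2)
    return gx


class SmallConvNet:
    """1-D convnet classifier over a selected feature vector.

    Architecture: conv(5, 32 filters)+ReLU+maxpool2 -> conv(3, 64 filters)
    +ReLU+maxpool2 -> flatten -> FC(flat) -> FC(256) -> FC(64) -> softmax
    over n_classes.  Treats the feature vector as a 1-D sequence; needs at
    least 8 features so both pooling stages keep a positive length.
    """

    def __init__(self, n_features: int, n_classes: int, lr: float = 1e-3,
                 seed: int = 0):
        if n_features < 8:
            raise ValueError("convnet evaluator needs at least 8 features")
        rng = np.random.default_rng(seed)
        self.n_features, self.n_classes = n_features, n_classes
        flat = 64 * (n_features // 2 // 2)
        self.flat = flat
        self.Wc1 = _he(rng, (32, 1, 5), 5)
        self.bc1 = np.zeros(32)
        self.Wc2 = _he(rng, (64, 32, 3), 32 * 3)
        self.bc2 = np.zeros(64)
        self.W1 = _he(rng, (flat, flat), flat)
        self.b1 = np.zeros(flat)
        self.W2 = _he(rng, (flat, 256), flat)
        self.b2 = np.zeros(256)
        self.W3 = _he(rng, (256, 64), 256)
        self.b3 = np.zeros(64)
        self.W4 = _he(rng, (64, n_classes), 64)
        self.b4 = np.zeros(n_classes)
        self.opt = Adam(lr=lr)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wc1, self.bc1, self.Wc2, self.bc2, self.W1, self.b1,
                self.W2, self.b2, self.W3, self.b3, self.W4, self.b4]

    def _forward(self, x: np.ndarray):
        B = x.shape[0]
        x3 = x[:, None, :]  # (B, 1, L)
        c1, cache1 = _conv1d_same(x3, self.Wc1, self.bc1)
        r1 = np.maximum(c1, 0.0)
        p1, pc1 = _maxpool2(r1)
        c2, cache2 = _conv1d_same(p1, self.Wc2, self.bc2)
        r2 = np.maximum(c2, 0.0)
        p2, pc2 = _maxpool2(r2)
        f = p2.reshape(B, -1)
        z1 = f @ self.W1 + self.b1
        h1 = np.maximum(z1, 0.0)
        z2 = h1 @ self.W2 + self.b2
        h2 = np.maximum(z2, 0.0)
        z3 = h2 @ self.W3 + self.b3
        h3 = np.maximum(z3, 0.0)
        logits = h3 @ self.W4 + self.b4
        cache = (x3, cache1, c1, pc1, p1, cache2, c2, pc2, p2, f,
                 z1, h1, z2, h2, z3, h3)
        return logits, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.atleast_2d(np.asarray(x, dtype=float)))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        """One Adam step of softmax cross-entropy on a batch."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.asarray(y, dtype=int)
        B = x.shape[0]
        logits, cache = self._forward(x)
        (x3, cache1, c1, pc1, p1, cache2, c2, pc2, p2, f,
         z1, h1, z2, h2, z3, h3) = cache
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        g = probs.copy()
        g[np.arange(B), y] -= 1.0
        g /= B
        gW4 = h3.T @ g
        gb4 = g.sum(axis=0)
        gh3 = g @ self.W4.T
        gz3 = gh3 * (z3 > 0)
        gW3 = h2.T @ gz3
        gb3 = gz3.sum(axis=0)
        gh2 = gz3 @ self.W3.T
        gz2 = gh2 * (z2 > 0)
        gW2 = h1.T @ gz2
        gb2 = gz2.sum(axis=0)
        gh1 = gz2 @ self.W2.T
        gz1 = gh1 * (z1 > 0)
        gW1 = f.T @ gz1
        gb1 = gz1.sum(axis=0)
        gf = gz1 @ self.W1.T
        gp2 = gf.reshape(p2.shape)
        gr2 = _maxpool2_backward(gp2, pc2)
        gc2 = gr2 * (c2 > 0)
        gp1, gWc2, gbc2 = _conv1d_same_backward(gc2, self.Wc2, cache2, p1.shape[2])
        gr1 = _maxpool2_backward(gp1, pc1)
        gc1 = gr1 * (c1 > 0)
        _, gWc1, gbc1 = _conv1d_same_backward(gc1, self.Wc1, cache1, x3.shape[2])
        self.opt.step(self.params, [gWc1, gbc1, gWc2, gbc2, gW1, gb1,
                                    gW2, gb2, gW3, gb3, gW4, gb4])
        return loss

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int = 100,
            batch_size: int = 32, seed: int = 0) -> list[float]:
        """Mini-batch training; returns the per-epoch mean loss trace."""
        rng = np.random.default_rng(seed)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.asarray(y, dtype=int)
        n = x.shape[0]
        trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_step(x[idx], y[idx]))
            trace.append(float(np.mean(losses)))
        return trace
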