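"""A small stacked-LSTM sequence classifier implemented on numpy.

Three LSTM layers are stacked, each feeding its full hidden-state
sequence to the next; the last layer's final hidden state passes through
a dense unit with a hard-sigmoid activation, giving one score in [0, 1]
per sample.  Gates use the hard sigmoid as well — the piecewise-linear
approximation ``clamp(0.2 x + 0.5, 0, 1)`` — which is cheap and works
well for binary classification heads.  Training is full backpropagation
through time with the Adam optimizer and binary cross-entropy loss.

Everything is deterministic given the seed: parameter initialisation and
mini-batch shuffling both derive from one ``numpy`` Generator, and all
arithmetic is plain dense linear algebra.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hard_sigmoid", "hard_sigmoid_grad", "LstmLayer", "StackedLstmClassifier"]

_EPS = 1e-7  # probability clip inside the cross-entropy


def hard_sigmoid(x: np.ndarray) -> np.ndarray:
    """Piecewise-linear sigmoid: ``clamp(0.2 x + 0.5, 0, 1)``."""
    return np.clip(0.2 * np.asarray(x) + 0.5, 0.0, 1.0)


def hard_sigmoid_grad(x: np.ndarray) -> np.ndarray:
    """Derivative of :func:`hard_sigmoid`: 0.2 inside (−2.5, 2.5), else 0."""
    x = np.asarray(x)
    return np.where((x > -2.5) & (x < 2.5), 0.2, 0.0)


class LstmLayer:
    """One LSTM layer (gate order i, f, g, o; hard-sigmoid gates, tanh cell)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_units = n_units
        limit_x = np.sqrt(6.0 / (n_in + 4 * n_units))
        limit_h = np.sqrt(6.0 / (n_units + 4 * n_units))
        self.Wx = rng.uniform(-limit_x, limit_x, size=(n_in, 4 * n_units))
        self.Wh = rng.uniform(-limit_h, limit_h, size=(n_units, 4 * n_units))
        self.b = np.zeros(4 * n_units)
        self.b[n_units : 2 * n_units] = 1.0  # forget-gate bias, standard trick
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Run the layer over a (T, N, n_in) sequence; returns (T, N, units)."""
        T, N, _ = X.shape
        u = self.n_units
        H = np.zeros((T, N, u))
        cache = []
        h = np.zeros((N, u))
        c = np.zeros((N, u))
        for t in range(T):
            z = X[t] @ self.Wx + h @ self.Wh + self.b
            zi, zf, zg, zo = z[:, :u], z[:, u : 2 * u], z[:, 2 * u : 3 * u], z[:, 3 * u :]
            i = hard_sigmoid(zi)
            f = hard_sigmoid(zf)
            g = np.tanh(zg)
            o = hard_sigmoid(zo)
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            H[t] = h
            cache.append((X[t], z, i, f, g, o, c_prev, tc, H[t - 1] if t > 0 else np.zeros((N, u))))
        self._cache = cache
        return H

    def backward(self, dH: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """BPTT given gradients w.r.t. every hidden output (T, N, units).

        Returns the gradient w.r.t. the input sequence and the parameter
        gradients [dWx, dWh, db].
        """
        cache = self._cache
        T = len(cache)
        N = dH.shape[1]
        u = self.n_units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros((T, N, self.n_in))
        dh_next = np.zeros((N, u))
        dc_next = np.zeros((N, u))
        for t in range(T - 1, -1, -1):
            x_t, z, i, f, g, o, c_prev, tc, h_prev = cache[t]
            zi, zf, zg, zo = z[:, :u], z[:, u : 2 * u], z[:, 2 * u : 3 * u], z[:, 3 * u :]
            dh = dH[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [
                    di * hard_sigmoid_grad(zi),
                    df * hard_sigmoid_grad(zf),
                    dg * (1.0 - g**2),
                    do * hard_sigmoid_grad(zo),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dX, [dWx, dWh, db]


class StackedLstmClassifier:
    """Sequence-to-vector network: stacked LSTM layers + hard-sigmoid unit."""

    def __init__(self, n_features: int, hidden_units: tuple[int, ...] = (64, 32, 16),
                 seed: int = 0):
        if any(u < 1 for u in hidden_units):
            raise ValueError("hidden layer sizes must be >= 1")
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        rng = np.random.default_rng(seed)
        self.hidden_units = tuple(hidden_units)
        self.n_features = n_features
        self.layers = []
        n_in = n_features
        for u in hidden_units:
            self.layers.append(LstmLayer(n_in, u, rng))
            n_in = u
        limit = np.sqrt(6.0 / (n_in + 1))
        self.W_out = rng.uniform(-limit, limit, size=(n_in, 1))
        self.b_out = np.zeros(1)
        self._rng = rng
        self._z_out = None
        self._h_last = None

    # ---- parameters -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        ps: list[np.ndarray] = []
        for layer in self.layers:
            ps.extend(layer.params)
        ps.extend([self.W_out, self.b_out])
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(weights) != len(own):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    # ---- forward / backward -----------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Score a batch: X is (N, T, F); returns (N,) values in [0, 1]."""
        H = np.transpose(np.asarray(X, dtype=float), (1, 0, 2))  # (T, N, F)
        for layer in self.layers:
            H = layer.forward(H)
        h_last = H[-1]
        z = h_last @ self.W_out + self.b_out
        self._h_last = h_last
        self._z_out = z
        return hard_sigmoid(z)[:, 0]

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray) -> tuple[float, list[np.ndarray]]:
        """Binary cross-entropy and gradients for a batch (runs forward)."""
        p = self.forward(X)
        y = np.asarray(y, dtype=float)
        N = y.size
        p_clip = np.clip(p, _EPS, 1.0 - _EPS)
        loss = float(-np.mean(y * np.log(p_clip) + (1.0 - y) * np.log(1.0 - p_clip)))
        dp = (p_clip - y) / (p_clip * (1.0 - p_clip)) / N
        dz = (dp * hard_sigmoid_grad(self._z_out[:, 0]))[:, None]
        dW_out = self._h_last.T @ dz
        db_out = dz.sum(axis=0)
        dh_last = dz @ self.W_out.T
        T = X.shape[1]
        grads_rev: list[list[np.ndarray]] = []
        dH = np.zeros((T, X.shape[0], self.hidden_units[-1]))
        dH[-1] = dh_last
        for layer in reversed(self.layers):
            dH, layer_grads = layer.backward(dH)
            grads_rev.append(layer_grads)
        grads: list[np.ndarray] = []
        for layer_grads in reversed(grads_rev):
            grads.extend(layer_grads)
        grads.extend([dW_out, db_out])
        return loss, grads

    def bce_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self.forward(X), _EPS, 1.0 - _EPS)
        y = np.asarray(y, dtype=float)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class AdamOptimizer:
    """Adam with bias correction, at the usual default rates."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
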