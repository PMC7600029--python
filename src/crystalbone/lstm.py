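"""A compact LSTM binary classifier over embedded code sequences.

Architecture: a single LSTM layer consumes the (L x embedding_dim)
sequence; its final hidden state and the temporal mean of its hidden
states are concatenated with a dense-ReLU transform of the static
features (age, sex, diagnosis count); a merge dense-ReLU layer and a
sigmoid head produce the fracture probability.  The temporal mean gives
the classifier a direct evidence-accumulation path over long windows that
a final state alone reaches only through a harder optimization.
Trained with binary cross-entropy, minibatch Adam, and manual
backpropagation through time.  Everything is plain vectorized numpy:
single-threaded, no dropout, bit-deterministic given the seed, so
``predict`` is a pure function of the fitted weights.

Front padding is zero rows; the LSTM consumes them before the real
tokens, and the pre-truncation diagnosis count is part of the statics so
the classifier can see how much history padding hides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


@dataclass(frozen=True)
class LSTMConfig:
    hidden: int = 64
    static_hidden: int = 32
    merge_hidden: int = 32
    lr: float = 1e-3
    epochs: int = 16
    batch_size: int = 64
    patience: int = 4  # early-stopping patience on validation AUROC
    seed: int = 0


class LSTMClassifier:
    """Sequence + statics -> fracture probability."""

    def __init__(self, input_dim: int, static_dim: int, config: LSTMConfig):
        self.config = config
        self.input_dim = input_dim
        self.static_dim = static_dim
        rng = np.random.default_rng(config.seed)
        H, S, M = config.hidden, config.static_hidden, config.merge_hidden

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-lim, lim, size=shape)

        self.params: dict[str, np.ndarray] = {
            "Wx": glorot((input_dim, 4 * H)),
            "Wh": glorot((H, 4 * H)),
            "b": np.zeros(4 * H),
            "Ws": glorot((static_dim, S)),
            "bs": np.zeros(S),
            "Wm": glorot((2 * H + S, M)),
            "bm": np.zeros(M),
            "w": glorot((M, 1)),
            "b0": np.zeros(1),
        }
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---- forward -------------------------------------------------------

    def _forward(self, X: np.ndarray, S: np.ndarray, cache: bool = False):
        p = self.params
        B, L, _ = X.shape
        H = self.config.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        h_sum = np.zeros((B, H))
        caches = []
        for t in range(L):
            a = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache:
                caches.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            h_sum += h
        h_mean = h_sum / L
        u_pre = S @ p["Ws"] + p["bs"]
        u = np.maximum(u_pre, 0.0)
        z_in = np.concatenate([h, h_mean, u], axis=1)
        z_pre = z_in @ p["Wm"] + p["bm"]
        z = np.maximum(z_pre, 0.0)
        logits = (z @ p["w"] + p["b0"]).ravel()
        probs = _sigmoid(logits)
        if not cache:
            return probs, None
        return probs, (X, S, caches, h, u_pre, u, z_in, z_pre, z)

    def predict_proba(self, X: np.ndarray, S: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(X, S, cache=False)
        return probs

    # ---- backward ------------------------------------------------------

    def _backward(self, probs, y, fwd_cache):
        p = self.params
        X, S, caches, h_last, u_pre, u, z_in, z_pre, z = fwd_cache
        B, L, _ = X.shape
        H = self.config.hidden
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogit = (probs - y) / len(y)  # BCE + sigmoid
        grads["w"] = z.T @ dlogit[:, None]
        grads["b0"] = np.array([dlogit.sum()])
        dz = (dlogit[:, None] @ p["w"].T) * (z_pre > 0)
        grads["Wm"] = z_in.T @ dz
        grads["bm"] = dz.sum(axis=0)
        dz_in = dz @ p["Wm"].T
        dh_last = dz_in[:, :H]
        dh_mean = dz_in[:, H : 2 * H] / L  # shared across every timestep
        du = dz_in[:, 2 * H :] * (u_pre > 0)
        grads["Ws"] = S.T @ du
        grads["bs"] = du.sum(axis=0)

        dc = np.zeros((B, H))
        dh = dh_last
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = caches[t]
            dh = dh + dh_mean
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += X[:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ p["Wh"].T
            dc = dc * f
        return grads

    def _adam_step(self, grads):
        self._adam_t += 1
        lr, b1, b2, eps = self.config.lr, 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def loss_and_grads(self, X, S, y):
        """One forward/backward pass; exposed for gradient checking."""
        probs, fwd = self._forward(X, S, cache=True)
        eps = 1e-12
        loss = -np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        return loss, self._backward(probs, y, fwd)

    def fit_epoch(self, X, S, y, rng: np.random.Generator) -> float:
        """One epoch of shuffled minibatch Adam; returns mean train loss."""
        n = len(y)
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, self.config.batch_size):
            sel = order[lo : lo + self.config.batch_size]
            loss, grads = self.loss_and_grads(X[sel], S[sel], y[sel])
            self._adam_step(grads)
            total += loss * len(sel)
        return total / n

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in snap.items()}
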