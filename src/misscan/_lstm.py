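"""Compact numpy LSTM sequence classifier.

A single (optionally bidirectional) LSTM layer followed by a dense softmax
layer over the classes, trained with Adam on masked categorical cross-entropy.
Backpropagation through time is implemented in full; everything is float32 and
deterministic given the seed. Batches are truncated to the longest real
sequence they contain, so tail padding costs nothing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMSequenceClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class _LSTMCell:
    """One direction's parameters: combined input+recurrent weights W of shape
    (F+H, 4H) with gate order (input, forget, cell, output)."""

    def __init__(self, n_features: int, n_hidden: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_hidden)
        self.W = rng.uniform(-bound, bound, size=(n_features + n_hidden, 4 * n_hidden)).astype(np.float32)
        self.b = np.zeros(4 * n_hidden, dtype=np.float32)
        self.b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.n_features = n_features
        self.n_hidden = n_hidden

    def forward(self, X: np.ndarray):
        """X: (B, T, F) -> hidden states (B, T, H) plus a BPTT cache."""
        B, T, F = X.shape
        H = self.n_hidden
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        Hs = np.empty((B, T, H), dtype=np.float32)
        cache = {
            "z": np.empty((B, T, F + H), dtype=np.float32),
            "i": np.empty((B, T, H), dtype=np.float32),
            "f": np.empty((B, T, H), dtype=np.float32),
            "g": np.empty((B, T, H), dtype=np.float32),
            "o": np.empty((B, T, H), dtype=np.float32),
            "c": np.empty((B, T, H), dtype=np.float32),
        }
        for t in range(T):
            z = np.concatenate([X[:, t, :], h], axis=1)
            a = z @ self.W + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            Hs[:, t] = h
            cache["z"][:, t] = z
            cache["i"][:, t] = i
            cache["f"][:, t] = f
            cache["g"][:, t] = g
            cache["o"][:, t] = o
            cache["c"][:, t] = c
        return Hs, cache

    def backward(self, dHs: np.ndarray, cache: dict):
        """dHs: (B, T, H) gradient w.r.t. the emitted hidden states."""
        B, T, _ = dHs.shape
        H = self.n_hidden
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, H), dtype=np.float32)
        dc_next = np.zeros((B, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][:, t], cache["f"][:, t], cache["g"][:, t], cache["o"][:, t]
            c = cache["c"][:, t]
            c_prev = cache["c"][:, t - 1] if t > 0 else np.zeros_like(c)
            tanh_c = np.tanh(c)
            dh = dHs[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            z = cache["z"][:, t]
            dW += z.T @ da
            db += da.sum(axis=0)
            dz = da @ self.W.T
            dh_next = dz[:, self.n_features :]
            dc_next = dc * f
        return dW, db


class LSTMSequenceClassifier:
    """Per-position sequence labeler: LSTM layer -> dense softmax."""

    def __init__(
        self,
        n_features: int,
        n_hidden: int,
        n_classes: int,
        seed: int = 0,
        bidirectional: bool = False,
    ):
        self.n_features = n_features
        self.n_hidden = n_hidden
        self.n_classes = n_classes
        self.bidirectional = bidirectional
        rng = np.random.default_rng(seed)
        self.cell_fw = _LSTMCell(n_features, n_hidden, rng)
        self.cell_bw = _LSTMCell(n_features, n_hidden, rng) if bidirectional else None
        out_dim = n_hidden * (2 if bidirectional else 1)
        bound = 1.0 / np.sqrt(out_dim)
        self.Wy = rng.uniform(-bound, bound, size=(out_dim, n_classes)).astype(np.float32)
        self.by = np.zeros(n_classes, dtype=np.float32)
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- parameter plumbing ------------------------------------------------

    def _params(self) -> dict[str, np.ndarray]:
        params = {"W_fw": self.cell_fw.W, "b_fw": self.cell_fw.b, "Wy": self.Wy, "by": self.by}
        if self.cell_bw is not None:
            params["W_bw"] = self.cell_bw.W
            params["b_bw"] = self.cell_bw.b
        return params

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self._params().items():
            v[...] = weights[k]

    # -- forward / backward -------------------------------------------------

    def _hidden(self, X: np.ndarray):
        Hs, cache_fw = self.cell_fw.forward(X)
        if self.cell_bw is None:
            return Hs, (cache_fw, None)
        Hs_bw, cache_bw = self.cell_bw.forward(X[:, ::-1, :])
        return np.concatenate([Hs, Hs_bw[:, ::-1, :]], axis=2), (cache_fw, cache_bw)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """X: (B, T, F) -> class probabilities (B, T, C)."""
        Hs, _ = self._hidden(X)
        return _softmax(Hs @ self.Wy + self.by)

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray, mask: np.ndarray):
        """Masked mean cross-entropy and gradients.

        X: (B, T, F); Y: (B, T) integer classes; mask: (B, T) bool over real
        positions. Padded positions contribute nothing to loss or gradients.
        """
        B, T, _ = X.shape
        H = self.n_hidden
        Hs, (cache_fw, cache_bw) = self._hidden(X)
        probs = _softmax(Hs @ self.Wy + self.by)
        n_real = int(mask.sum())
        if n_real == 0:
            raise ValueError("batch contains no real positions")
        eps = 1e-12
        picked = np.take_along_axis(probs, Y[..., None], axis=2)[..., 0]
        loss = float(-(np.log(picked + eps) * mask).sum() / n_real)

        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, Y[..., None], np.take_along_axis(dlogits, Y[..., None], axis=2) - 1.0, axis=2
        )
        dlogits *= mask[..., None].astype(np.float32) / np.float32(n_real)

        flatH = Hs.reshape(B * T, -1)
        flatD = dlogits.reshape(B * T, -1)
        dWy = (flatH.T @ flatD).astype(np.float32)
        dby = flatD.sum(axis=0).astype(np.float32)
        dHs = (dlogits @ self.Wy.T).astype(np.float32)

        grads = {"Wy": dWy, "by": dby}
        dW_fw, db_fw = self.cell_fw.backward(dHs[:, :, :H], cache_fw)
        grads["W_fw"], grads["b_fw"] = dW_fw, db_fw
        if self.cell_bw is not None:
            dW_bw, db_bw = self.cell_bw.backward(dHs[:, ::-1, H:], cache_bw)
            grads["W_bw"], grads["b_bw"] = dW_bw, db_bw
        return loss, grads

    # -- Adam ----------------------------------------------------------------

    def adam_step(self, grads: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for name, param in self._params().items():
            g = grads[name]
            if name not in self._adam_state:
                self._adam_state[name] = (np.zeros_like(param), np.zeros_like(param))
            m, v = self._adam_state[name]
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            param -= (lr * m_hat / (np.sqrt(v_hat) + eps)).astype(np.float32)

    # -- training loop ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        mask: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        rng: np.random.Generator,
    ) -> list[float]:
        """Train on (N, T, F) inputs; returns per-epoch mean losses.

        Each batch is truncated to its longest real sequence before the
        forward pass.
        """
        n = X.shape[0]
        lengths = mask.sum(axis=1)
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                t_eff = int(lengths[idx].max())
                if t_eff == 0:
                    continue
                loss, grads = self.loss_and_grads(
                    X[idx, :t_eff], Y[idx, :t_eff], mask[idx, :t_eff]
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss ({loss}); try a lower learning rate"
                    )
                self.adam_step(grads, learning_rate)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history
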