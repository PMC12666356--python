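"""Compact numpy recurrent classifiers for univariate sequences.

Implements the gated recurrent unit

    z_t = sigma(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigma(W_r x_t + U_r h_{t-1} + b_r)
    h_t = (1 - z_t) (.) h_{t-1} + z_t (.) tanh(W_h x_t + U_h (r_t (.) h_{t-1}) + b_h)

and the standard LSTM cell, trained by backpropagation through time with
softmax cross-entropy and the Adam optimizer.  Each input row is treated
as a univariate sequence (one value per time step); a dropout layer sits
between the final hidden state and the dense class-probability head.

The GRU uses separate input-side and recurrent-side bias vectors per gate
with the reset gate applied after the recurrent matmul (the convention
under which a 64-unit cell on univariate input has 3*(64*65 + 128) =
12,864 parameters).  With h_0 = 0 and a zero recurrent bias this reduces
exactly to the single-bias equations above, which is what the unit-level
hand oracles exercise.  The LSTM uses a single bias per gate
(4*(64*65 + 64) = 16,896 parameters at 64 units).
"""

from __future__ import annotations

import numpy as np

_SIGMOID_CLIP = 60.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_SIGMOID_CLIP, _SIGMOID_CLIP)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _orthogonal(rng: np.random.Generator, n: int, dtype) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    q *= np.sign(np.diag(r))
    return np.ascontiguousarray(q).astype(dtype)


def _glorot(rng: np.random.Generator, n: int, m: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (n + m))
    return rng.uniform(-limit, limit, size=(n, m)).astype(dtype)


def count_trainable_parameters(
    units: int, input_dim: int, n_classes: int, cell: str = "gru"
) -> list[tuple[str, int]]:
    """Per-layer trainable parameter counts for the sequence classifier.

    GRU uses the double-bias gate convention 3*(h*(i+h) + 2h); LSTM the
    single-bias convention 4*(h*(i+h) + h); the dense head is h*K + K.
    Returns ``[(layer, count), ..., ("total", total)]``.
    """
    h, i, k = units, input_dim, n_classes
    if cell == "gru":
        rec = 3 * (h * (i + h) + 2 * h)
    elif cell == "lstm":
        rec = 4 * (h * (i + h) + h)
    else:
        raise ValueError(f"unknown cell {cell!r}")
    layers = [(cell, rec), ("dropout", 0), ("dense", h * k + k)]
    return layers + [("total", sum(c for _, c in layers))]


class RecurrentClassifier:
    """GRU/LSTM sequence classifier over univariate inputs.

    Parameters
    ----------
    cell:
        ``"gru"`` or ``"lstm"``.
    units:
        Hidden-state width.
    dropout:
        Drop probability applied to the final hidden state during
        training (inverted dropout; inference is deterministic).
    standardize:
        Z-score each time-step column by training statistics before the
        recurrence; raw EEG amplitudes otherwise saturate the gates.
    """

    def __init__(
        self,
        cell: str = "gru",
        units: int = 64,
        dropout: float = 0.2,
        epochs: int = 10,
        batch_size: int = 64,
        learning_rate: float = 3e-3,
        seed: int = 0,
        standardize: bool = True,
    ) -> None:
        if cell not in ("gru", "lstm"):
            raise ValueError(f"unknown cell {cell!r}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.cell = cell
        self.units = units
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.standardize = standardize
        self._fitted = False

    # -- parameters --------------------------------------------------------
    def _init_params(self, rng: np.random.Generator, n_classes: int) -> None:
        h = self.units
        g = 3 if self.cell == "gru" else 4
        dt = np.float32
        self.W = _glorot(rng, 1, g * h, dt)
        self.U = np.concatenate([_orthogonal(rng, h, dt) for _ in range(g)], axis=1)
        self.b_in = np.zeros(g * h, dtype=dt)
        # recurrent-side bias only exists for the gru double-bias convention
        self.b_rec = np.zeros(g * h, dtype=dt) if self.cell == "gru" else None
        self.Wd = _glorot(rng, h, n_classes, dt)
        self.bd = np.zeros(n_classes, dtype=dt)

    def _param_list(self) -> list[np.ndarray]:
        ps = [self.W, self.U, self.b_in, self.Wd, self.bd]
        if self.b_rec is not None:
            ps.insert(3, self.b_rec)
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self._param_list()))

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray, cache: bool = False):
        """Run the recurrence; X is (B, T) float32, returns final h (B, h)."""
        B, T = X.shape
        h = self.units
        XW = X[:, :, None] * self.W[0][None, None, :] + self.b_in  # (B,T,g*h)
        ht = np.zeros((B, h), dtype=np.float32)
        caches = []
        if self.cell == "gru":
            Uz, Ur, Uc = self.U[:, :h], self.U[:, h : 2 * h], self.U[:, 2 * h :]
            bz, br, bc = self.b_rec[:h], self.b_rec[h : 2 * h], self.b_rec[2 * h :]
            for t in range(T):
                hu_z = ht @ Uz + bz
                hu_r = ht @ Ur + br
                hu_c = ht @ Uc + bc
                z = _sigmoid(XW[:, t, :h] + hu_z)
                r = _sigmoid(XW[:, t, h : 2 * h] + hu_r)
                c = np.tanh(XW[:, t, 2 * h :] + r * hu_c)
                h_new = (1.0 - z) * ht + z * c
                if cache:
                    caches.append((ht, z, r, c, hu_c))
                ht = h_new
            return (ht, XW, caches) if cache else ht
        # lstm
        ct = np.zeros((B, h), dtype=np.float32)
        for t in range(T):
            a = XW[:, t] + ht @ self.U
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_new = f * ct + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if cache:
                caches.append((ht, ct, i, f, g, o, tanh_c))
            ht, ct = h_new, c_new
        return (ht, XW, caches) if cache else ht

    def _backward(self, X, XW, caches, dh):
        """BPTT from the gradient on the final hidden state."""
        B, T = X.shape
        h = self.units
        dXW = np.zeros_like(XW)
        dU = np.zeros_like(self.U)
        if self.cell == "gru":
            Uz, Ur, Uc = self.U[:, :h], self.U[:, h : 2 * h], self.U[:, 2 * h :]
            db_rec = np.zeros_like(self.b_rec)
            for t in range(T - 1, -1, -1):
                h_prev, z, r, c, hu_c = caches[t]
                dz = dh * (c - h_prev)
                dc = dh * z
                dh_prev = dh * (1.0 - z)
                dc_a = dc * (1.0 - c * c)
                dr = dc_a * hu_c
                dhu_c = dc_a * r
                dz_a = dz * z * (1.0 - z)
                dr_a = dr * r * (1.0 - r)
                dXW[:, t, :h] = dz_a
                dXW[:, t, h : 2 * h] = dr_a
                dXW[:, t, 2 * h :] = dc_a
                dU[:, :h] += h_prev.T @ dz_a
                dU[:, h : 2 * h] += h_prev.T @ dr_a
                dU[:, 2 * h :] += h_prev.T @ dhu_c
                db_rec[:h] += dz_a.sum(0)
                db_rec[h : 2 * h] += dr_a.sum(0)
                db_rec[2 * h :] += dhu_c.sum(0)
                dh = dh_prev + dz_a @ Uz.T + dr_a @ Ur.T + dhu_c @ Uc.T
            extra = [db_rec]
        else:
            dc = np.zeros((B, h), dtype=np.float32)
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
                do = dh * tanh_c
                dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
                di, df, dg = dc * g, dc * c_prev, dc * i
                da = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g * g),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dXW[:, t] = da
                dU += h_prev.T @ da
                dh = da @ self.U.T
                dc = dc * f
            extra = []
        dW = np.einsum("bt,btg->g", X, dXW)[None, :]
        db_in = dXW.sum(axis=(0, 1))
        return [dW.astype(np.float32), dU, db_in] + extra

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y) -> "RecurrentClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to fit")
        k = self.classes_.size
        y_idx = np.searchsorted(self.classes_, y)

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
        else:
            self.mean_, self.scale_ = None, None
        Xs = self._transform(X)

        rng = np.random.default_rng(self.seed)
        self._init_params(rng, k)
        params = self._param_list()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        n = X.shape[0]
        self.history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, epoch_hits = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], y_idx[idx]
                hT, XW, caches = self._forward(xb, cache=True)
                if self.dropout > 0:
                    mask = (rng.uniform(size=hT.shape) >= self.dropout).astype(
                        np.float32
                    ) / (1.0 - self.dropout)
                    hd = hT * mask
                else:
                    mask = None
                    hd = hT
                logits = hd @ self.Wd + self.bd
                probs = _softmax(logits)
                B = len(idx)
                epoch_loss += -np.log(probs[np.arange(B), yb] + 1e-12).sum()
                epoch_hits += int((probs.argmax(1) == yb).sum())
                dlogits = probs.copy()
                dlogits[np.arange(B), yb] -= 1.0
                dlogits /= B
                dWd = hd.T @ dlogits
                dbd = dlogits.sum(0)
                dh = dlogits @ self.Wd.T
                if mask is not None:
                    dh = dh * mask
                grads = self._backward(xb, XW, caches, dh.astype(np.float32))
                grads += [dWd.astype(np.float32), dbd.astype(np.float32)]
                step += 1
                lr_t = (
                    self.learning_rate
                    * np.sqrt(1 - beta2**step)
                    / (1 - beta1**step)
                )
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
            self.history_.append(
                {"loss": epoch_loss / n, "accuracy": epoch_hits / n}
            )
        self._fitted = True
        return self

    # -- inference ---------------------------------------------------------
    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.mean_ is not None:
            X = (X - self.mean_) / self.scale_
        return X

    def decision_hidden(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Final hidden states h_T, one row per input sequence."""
        if not self._fitted:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.shape[0] == 0:
            return np.empty((0, self.units), dtype=np.float32)
        if self.mean_ is not None and X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"input width {X.shape[1]} does not match fitted width {self.mean_.shape[0]}"
            )
        Xs = self._transform(X)
        outs = [
            self._forward(Xs[i : i + batch_size])
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = self.decision_hidden(X)
        if h.shape[0] == 0:
            return np.empty((0, self.Wd.shape[1]))
        return _softmax(h @ self.Wd + self.bd).astype(np.float64)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
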