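"""Minimal recurrent neural-network engine.

Implements exactly what the emotion classifiers need — LSTM and
bidirectional LSTM layers, inter-layer dropout, a dense softmax head,
categorical cross-entropy, and the SGD / RMSprop / Adam optimizers — as
plain NumPy with full backpropagation through time.

Conventions follow the common deep-learning ones so closed-form
parameter counts transfer: an LSTM layer over inputs of width ``d`` with
``u`` units holds kernels ``Wx (d, 4u)``, recurrent kernel ``Wh (u, 4u)``
and bias ``b (4u,)`` — ``4((d + u + 1)u)`` trainable parameters — with
gate order (input, forget, cell, output), sigmoid gates, tanh cell
input/output, Glorot-uniform kernel init, orthogonal recurrent init and
unit forget-gate bias.  A bidirectional layer holds an independent
parameter set per direction and concatenates the two outputs.

Everything is deterministic given the ``numpy.random.Generator`` passed
for initialization, dropout masks and batch shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LSTMLayer",
    "BiLSTMLayer",
    "Dropout",
    "Dense",
    "SequenceClassifier",
    "SGD",
    "RMSprop",
    "Adam",
    "make_optimizer",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, n: int, dtype) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(dtype)


class _Layer:
    trainable = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class LSTMLayer(_Layer):
    """Single-direction LSTM.

    ``return_sequences=True`` emits the full hidden sequence (B, T, u);
    otherwise only the final hidden state (B, u).
    """

    def __init__(
        self,
        input_dim: int,
        units: int,
        return_sequences: bool,
        rng: np.random.Generator,
        dtype=np.float32,
        go_backwards: bool = False,
    ):
        self.input_dim = input_dim
        self.units = units
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.dtype = dtype
        u = units
        self.Wx = _glorot_uniform(rng, (input_dim, 4 * u), dtype)
        self.Wh = np.concatenate(
            [_orthogonal(rng, u, dtype) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * u, dtype=dtype)
        self.b[u : 2 * u] = 1.0  # unit forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return 4 * ((self.input_dim + self.units + 1) * self.units)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if self.go_backwards:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        u = self.units
        xW = x.reshape(B * T, -1) @ self.Wx
        xW = xW.reshape(B, T, 4 * u) + self.b

        h = np.zeros((B, u), dtype=self.dtype)
        c = np.zeros((B, u), dtype=self.dtype)
        gates = np.empty((B, T, 4 * u), dtype=self.dtype)  # post-activation i,f,g,o
        h_prev = np.empty((B, T, u), dtype=self.dtype)
        c_prev = np.empty((B, T, u), dtype=self.dtype)
        tanh_c = np.empty((B, T, u), dtype=self.dtype)
        h_seq = np.empty((B, T, u), dtype=self.dtype)
        for t in range(T):
            z = xW[:, t, :] + h @ self.Wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            h_prev[:, t] = h
            c_prev[:, t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[:, t, :u] = i
            gates[:, t, u : 2 * u] = f
            gates[:, t, 2 * u : 3 * u] = g
            gates[:, t, 3 * u :] = o
            tanh_c[:, t] = tc
            h_seq[:, t] = h
        self._cache = (x, gates, h_prev, c_prev, tanh_c)
        if self.return_sequences:
            # reverse back so outputs align with original time order
            return h_seq[:, ::-1, :] if self.go_backwards else h_seq
        return h_seq[:, -1, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, gates, h_prev, c_prev, tanh_c = self._cache
        B, T, _ = x.shape
        u = self.units
        if self.return_sequences:
            dh_seq = dout[:, ::-1, :] if self.go_backwards else dout
        else:
            dh_seq = None

        dz_all = np.empty((B, T, 4 * u), dtype=self.dtype)
        dh_next = np.zeros((B, u), dtype=self.dtype)
        dc_next = np.zeros((B, u), dtype=self.dtype)
        WhT = self.Wh.T
        for t in range(T - 1, -1, -1):
            dh = dh_next.copy()
            if dh_seq is not None:
                dh += dh_seq[:, t]
            elif t == T - 1:
                dh += dout
            i = gates[:, t, :u]
            f = gates[:, t, u : 2 * u]
            g = gates[:, t, 2 * u : 3 * u]
            o = gates[:, t, 3 * u :]
            tc = tanh_c[:, t]
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev[:, t]
            dg = dc * i
            dz = dz_all[:, t]
            dz[:, :u] = di * i * (1.0 - i)
            dz[:, u : 2 * u] = df * f * (1.0 - f)
            dz[:, 2 * u : 3 * u] = dg * (1.0 - g * g)
            dz[:, 3 * u :] = do * o * (1.0 - o)
            dh_next = dz @ WhT
            dc_next = dc * f

        flat_dz = dz_all.reshape(B * T, 4 * u)
        self.dWx[...] = x.reshape(B * T, -1).T @ flat_dz
        self.dWh[...] = h_prev.reshape(B * T, u).T @ flat_dz
        self.db[...] = flat_dz.sum(axis=(0,))
        dx = (flat_dz @ self.Wx.T).reshape(B, T, -1)
        if self.go_backwards:
            dx = dx[:, ::-1, :]
        self._cache = None
        return dx


class BiLSTMLayer(_Layer):
    """Bidirectional LSTM: independent forward- and backward-time passes
    whose outputs are concatenated along the feature axis."""

    def __init__(self, input_dim, units, return_sequences, rng, dtype=np.float32):
        self.units = units
        self.return_sequences = return_sequences
        self.fwd = LSTMLayer(input_dim, units, return_sequences, rng, dtype)
        self.bwd = LSTMLayer(input_dim, units, return_sequences, rng, dtype, go_backwards=True)

    @property
    def n_parameters(self) -> int:
        return self.fwd.n_parameters + self.bwd.n_parameters

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()

    def forward(self, x, train=False, rng=None):
        yf = self.fwd.forward(x, train, rng)
        yb = self.bwd.forward(x, train, rng)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dout):
        u = self.units
        if self.return_sequences:
            df, db = dout[..., :u], dout[..., u:]
        else:
            df, db = dout[:, :u], dout[:, u:]
        return self.fwd.backward(df) + self.bwd.backward(db)


class Dropout(_Layer):
    """Inverted dropout; identity at inference."""

    trainable = False

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(_Layer):
    """Affine map on the final feature axis."""

    def __init__(self, input_dim, units, rng, dtype=np.float32):
        self.W = _glorot_uniform(rng, (input_dim, units), dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SequenceClassifier:
    """A stack of layers ending in a softmax head, trained with
    categorical cross-entropy on one-hot labels."""

    def __init__(self, layers: list[_Layer]):
        self.layers = layers

    @property
    def n_parameters(self) -> int:
        return sum(
            getattr(layer, "n_parameters", 0)
            for layer in self.layers
            if layer.trainable
        )

    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.grads())
        return out

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Class probabilities, rows summing to 1."""
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return softmax(out)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Hard class indices, computed in inference mode."""
        preds = []
        for start in range(0, len(x), batch_size):
            preds.append(
                np.argmax(self.forward(x[start : start + batch_size]), axis=1)
            )
        return np.concatenate(preds) if preds else np.zeros(0, dtype=int)

    def _backward_from_probs(self, probs: np.ndarray, y: np.ndarray) -> None:
        dlogits = (probs - y) / len(y)
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def train_epoch(
        self,
        x: np.ndarray,
        y: np.ndarray,
        batch_size: int,
        optimizer: "Optimizer",
        rng: np.random.Generator,
    ) -> float:
        """One pass over (x, y) in shuffled mini-batches; returns the mean
        training loss."""
        order = rng.permutation(len(x))
        total = 0.0
        for start in range(0, len(x), batch_size):
            batch = order[start : start + batch_size]
            xb, yb = x[batch], y[batch]
            probs = self.forward(xb, train=True, rng=rng)
            total += _cross_entropy(probs, yb) * len(batch)
            self._backward_from_probs(probs, yb)
            optimizer.step(self.params(), self.grads())
        return total / len(x)

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256):
        """(mean loss, accuracy) in inference mode."""
        loss = 0.0
        correct = 0
        for start in range(0, len(x), batch_size):
            xb, yb = x[start : start + batch_size], y[start : start + batch_size]
            probs = self.forward(xb)
            loss += _cross_entropy(probs, yb) * len(xb)
            correct += int((np.argmax(probs, 1) == np.argmax(yb, 1)).sum())
        return loss / len(x), correct / len(x)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.sum(y * np.log(probs + eps), axis=1)))


class Optimizer:
    def __init__(self, learning_rate: float):
        if learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = learning_rate

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    """Plain stochastic gradient descent (no momentum)."""

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= (self.lr * g).astype(p.dtype)


class RMSprop(Optimizer):
    def __init__(self, learning_rate: float, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(learning_rate)
        self.rho, self.eps = rho, eps
        self._v: dict[int, np.ndarray] = {}

    def step(self, params, grads):
        for idx, (p, g) in enumerate(zip(params, grads)):
            v = self._v.setdefault(idx, np.zeros_like(p, dtype=np.float64))
            v *= self.rho
            v += (1.0 - self.rho) * np.square(g, dtype=np.float64)
            p -= (self.lr * g / (np.sqrt(v) + self.eps)).astype(p.dtype)


class Adam(Optimizer):
    def __init__(self, learning_rate: float, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params, grads):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(idx, np.zeros_like(p, dtype=np.float64))
            v = self._v.setdefault(idx, np.zeros_like(p, dtype=np.float64))
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g, dtype=np.float64)
            mhat = m / (1.0 - b1**self._t)
            vhat = v / (1.0 - b2**self._t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def make_optimizer(name: str, learning_rate: float) -> Optimizer:
    table = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}
    if name not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[name](learning_rate)
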