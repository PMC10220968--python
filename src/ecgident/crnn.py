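"""The 1-D convolutional-recurrent network (CRNN) used for deep feature
extraction, implemented directly on numpy.

Architecture (in order): two sequence-returning LSTM layers (128, 64 units)
on the 94*k-sample beat treated as a length-94*k sequence of scalars; three
same-padded 1-D convolutions (32xk3, 64xk5, 32xk8, ReLU); dropout 0.5;
max-pool (size 5, stride 2, same padding); dropout 0.2; flatten; dense 256
(ReLU); dense 128 (ReLU, the biometric feature layer); dense softmax over
subjects.  Training is mini-batch Adam on categorical cross-entropy with
full backpropagation through time; everything is deterministic under a seed
on a single thread.

`count_parameters` gives the closed-form learnable-parameter table
(LSTM: 4(h(d+h)+h); conv: c*w*f+f; dense: (m+1)u) and is cross-checked in
tests against the realized network's weight arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidInputError, InvalidStateError

__all__ = [
    "CRNNConfig",
    "ParamTable",
    "TrainSpec",
    "count_parameters",
    "build_crnn",
    "train_crnn",
    "extract_deep_features",
    "CRNN",
]


@dataclass(frozen=True)
class CRNNConfig:
    """Complete layer specification of the network."""

    seq_len: int = 94
    n_classes: int = 2
    input_dim: int = 1
    lstm_units: tuple[int, ...] = (128, 64)
    conv_specs: tuple[tuple[int, int], ...] = ((32, 3), (64, 5), (32, 8))
    dropout_rates: tuple[float, float] = (0.5, 0.2)
    pool_size: int = 5
    pool_stride: int = 2
    dense_units: tuple[int, ...] = (256, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise InvalidConfigError("n_classes must be >= 1")
        if self.seq_len < self.pool_size:
            raise InvalidConfigError("seq_len must be at least the pooling size")

    @property
    def pooled_len(self) -> int:
        return -(-self.seq_len // self.pool_stride)  # ceil

    @property
    def flatten_len(self) -> int:
        return self.conv_specs[-1][0] * self.pooled_len


@dataclass
class ParamTable:
    """Per-layer learnable parameter counts, mirroring the layer order."""

    rows: list[tuple[str, str, int]]

    @property
    def total(self) -> int:
        return sum(r[2] for r in self.rows)

    def counts(self) -> list[int]:
        return [r[2] for r in self.rows if r[2] > 0]

    def __str__(self) -> str:
        lines = [f"{'Layer':<10} {'Output shape':<16} {'Params':>10}"]
        for name, shape, count in self.rows:
            lines.append(f"{name:<10} {shape:<16} {count:>10,}")
        lines.append(f"{'Total':<10} {'':<16} {self.total:>10,}")
        return "\n".join(lines)


@dataclass
class TrainSpec:
    """Optimization protocol (adaptive-moment descent on cross-entropy)."""

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise InvalidConfigError("learning rate, epochs and batch size must be positive")


def count_parameters(config: CRNNConfig) -> ParamTable:
    """Closed-form learnable-parameter table for the architecture."""
    rows: list[tuple[str, str, int]] = []
    t = config.seq_len
    d = config.input_dim
    for h in config.lstm_units:
        rows.append(("LSTM", f"(0, {t}, {h})", 4 * (h * (d + h) + h)))
        d = h
    c = d
    for f, w in config.conv_specs:
        rows.append(("Conv1D", f"(0, {t}, {f})", c * w * f + f))
        c = f
    rows.append(("Dropout", f"(0, {t}, {c})", 0))
    rows.append(("Maxpool", f"(0, {config.pooled_len}, {c})", 0))
    rows.append(("Dropout", f"(0, {config.pooled_len}, {c})", 0))
    rows.append(("Flatten", f"(0, {config.flatten_len})", 0))
    m = config.flatten_len
    for u in config.dense_units:
        rows.append(("Dense", f"(0, {u})", (m + 1) * u))
        m = u
    rows.append(("Dense", f"(0, {config.n_classes})", (m + 1) * config.n_classes))
    return ParamTable(rows=rows)


# ---------------------------------------------------------------------------
# numpy building blocks
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class _LSTM:
    """Sequence-returning LSTM (gate order i, f, g, o; forget bias 1)."""

    def __init__(self, rng, d: int, h: int, dtype):
        self.d, self.h = d, h
        self.Wx = _glorot(rng, (d, 4 * h), d, 4 * h, dtype)
        self.Wh = _glorot(rng, (h, 4 * h), h, 4 * h, dtype)
        self.b = np.zeros(4 * h, dtype=dtype)
        self.b[h: 2 * h] = 1.0

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x, cache: bool):
        B, T, _ = x.shape
        h, dtype = self.h, x.dtype
        hs = np.zeros((B, T, h), dtype=dtype)
        ht = np.zeros((B, h), dtype=dtype)
        ct = np.zeros((B, h), dtype=dtype)
        gates = np.empty((B, T, 4 * h), dtype=dtype) if cache else None
        cs = np.empty((B, T, h), dtype=dtype) if cache else None
        xW = x.reshape(B * T, self.d) @ self.Wx
        xW = xW.reshape(B, T, 4 * h) + self.b
        for t in range(T):
            z = xW[:, t] + ht @ self.Wh
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h: 2 * h])
            g = np.tanh(z[:, 2 * h: 3 * h])
            o = _sigmoid(z[:, 3 * h:])
            ct = f * ct + i * g
            ht = o * np.tanh(ct)
            hs[:, t] = ht
            if cache:
                gates[:, t, :h] = i
                gates[:, t, h: 2 * h] = f
                gates[:, t, 2 * h: 3 * h] = g
                gates[:, t, 3 * h:] = o
                cs[:, t] = ct
        self._cache = (x, gates, cs) if cache else None
        return hs

    def backward(self, dhs):
        x, gates, cs = self._cache
        B, T, _ = x.shape
        h = self.h
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, h), dtype=x.dtype)
        dc_next = np.zeros((B, h), dtype=x.dtype)
        dz_all = np.empty((B, T, 4 * h), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h: 2 * h]
            g = gates[:, t, 2 * h: 3 * h]
            o = gates[:, t, 3 * h:]
            ct = cs[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(ct)
            h_prev = None  # filled via matmul accumulation below
            tanh_c = np.tanh(ct)
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c * tanh_c) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = dz_all[:, t]
            dz[:, :h] = di * i * (1 - i)
            dz[:, h: 2 * h] = df * f * (1 - f)
            dz[:, 2 * h: 3 * h] = dg * (1 - g * g)
            dz[:, 3 * h:] = do * o * (1 - o)
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        # accumulate weight grads in bulk
        hs_prev = np.zeros((B, T, h), dtype=x.dtype)
        # previous hidden states: o*tanh(c) shifted by one step
        o_all = gates[:, :, 3 * h:]
        hs_prev[:, 1:] = o_all[:, :-1] * np.tanh(cs[:, :-1])
        dz_flat = dz_all.reshape(B * T, 4 * h)
        dWx += x.reshape(B * T, self.d).T @ dz_flat
        dWh += hs_prev.reshape(B * T, h).T @ dz_flat
        db += dz_flat.sum(axis=0)
        dx = (dz_flat @ self.Wx.T).reshape(B, T, self.d)
        self._cache = None
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class _Conv1D:
    """Same-padded 1-D convolution with ReLU."""

    def __init__(self, rng, c_in: int, filters: int, width: int, dtype):
        self.c_in, self.f, self.w = c_in, filters, width
        self.W = _glorot(rng, (width, c_in, filters), width * c_in, filters, dtype)
        self.b = np.zeros(filters, dtype=dtype)

    def params(self):
        return {"W": self.W, "b": self.b}

    def _cols(self, x):
        B, T, C = x.shape
        left = (self.w - 1) // 2
        right = self.w - 1 - left
        xpad = np.pad(x, ((0, 0), (left, right), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xpad, self.w, axis=1)
        # (B, T, C, w) -> (B, T, w, C)
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)), left

    def forward(self, x, cache: bool):
        B, T, _ = x.shape
        cols, left = self._cols(x)
        z = cols.reshape(B * T, self.w * self.c_in) @ self.W.reshape(self.w * self.c_in, self.f)
        z = z.reshape(B, T, self.f) + self.b
        out = np.maximum(z, 0)
        if cache:
            self._cache = (cols, x.shape, left, z > 0)
        return out

    def backward(self, dout):
        cols, xshape, left, mask = self._cache
        B, T, C = xshape
        dz = (dout * mask).reshape(B * T, self.f)
        cols_flat = cols.reshape(B * T, self.w * self.c_in)
        dW = (cols_flat.T @ dz).reshape(self.w, self.c_in, self.f)
        db = dz.sum(axis=0)
        dcols = (dz @ self.W.reshape(self.w * self.c_in, self.f).T).reshape(B, T, self.w, C)
        right = self.w - 1 - left
        dxpad = np.zeros((B, T + left + right, C), dtype=dout.dtype)
        for j in range(self.w):
            dxpad[:, j: j + T] += dcols[:, :, j]
        dx = dxpad[:, left: left + T]
        self._cache = None
        return dx, {"W": dW, "b": db}


class _MaxPool:
    """Same-padded max pooling over time."""

    def __init__(self, size: int, stride: int):
        self.size, self.stride = size, stride

    def forward(self, x, cache: bool):
        B, T, C = x.shape
        out_len = -(-T // self.stride)
        pad_total = max((out_len - 1) * self.stride + self.size - T, 0)
        left = pad_total // 2
        xpad = np.full((B, T + pad_total, C), -np.inf, dtype=x.dtype)
        xpad[:, left: left + T] = x
        win = np.lib.stride_tricks.sliding_window_view(xpad, self.size, axis=1)
        win = win[:, :: self.stride][:, :out_len]  # (B, out_len, C, size)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (arg, left, x.shape, pad_total)
        return out

    def backward(self, dout):
        arg, left, xshape, pad_total = self._cache
        B, T, C = xshape
        out_len = dout.shape[1]
        dxpad = np.zeros((B, T + pad_total, C), dtype=dout.dtype)
        starts = np.arange(out_len) * self.stride
        pos = starts[None, :, None] + arg  # (B, out_len, C) in padded coords
        bidx = np.arange(B)[:, None, None]
        cidx = np.arange(C)[None, None, :]
        np.add.at(dxpad, (bidx, pos, cidx), dout)
        self._cache = None
        return dxpad[:, left: left + T]


class _Dense:
    def __init__(self, rng, m: int, u: int, relu: bool, dtype):
        self.W = _glorot(rng, (m, u), m, u, dtype)
        self.b = np.zeros(u, dtype=dtype)
        self.relu = relu

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, cache: bool):
        z = x @ self.W + self.b
        out = np.maximum(z, 0) if self.relu else z
        if cache:
            self._cache = (x, z > 0 if self.relu else None)
        return out

    def backward(self, dout):
        x, mask = self._cache
        dz = dout * mask if self.relu else dout
        dW = x.T @ dz
        db = dz.sum(axis=0)
        dx = dz @ self.W.T
        self._cache = None
        return dx, {"W": dW, "b": db}


class CRNN:
    """Realized network; build with :func:`build_crnn`."""

    def __init__(self, config: CRNNConfig, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(config.seed)
        self.lstms = []
        d = config.input_dim
        for h in config.lstm_units:
            self.lstms.append(_LSTM(rng, d, h, self.dtype))
            d = h
        self.convs = []
        c = d
        for f, w in config.conv_specs:
            self.convs.append(_Conv1D(rng, c, f, w, self.dtype))
            c = f
        self.pool = _MaxPool(config.pool_size, config.pool_stride)
        m = config.flatten_len
        self.denses = []
        for u in config.dense_units:
            self.denses.append(_Dense(rng, m, u, relu=True, dtype=self.dtype))
            m = u
        self.denses.append(_Dense(rng, m, config.n_classes, relu=False, dtype=self.dtype))
        self.trained = False
        self.history: dict[str, list[float]] | None = None

    # -- introspection ------------------------------------------------------

    def _layers(self):
        return [*self.lstms, *self.convs, *self.denses]

    def parameter_counts(self) -> list[int]:
        """Parameter count per learnable layer from the allocated arrays."""
        return [sum(p.size for p in layer.params().values()) for layer in self._layers()]

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            for name, arr in layer.params().items():
                out[f"layer{i}/{name}"] = arr
        return out

    # -- forward ------------------------------------------------------------

    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != self.config.seq_len:
            raise InvalidInputError(
                f"expected beats of length {self.config.seq_len}, got shape {X.shape}"
            )
        return X

    def _forward(self, X, train: bool, rng=None, upto: str = "softmax"):
        cache = train
        h = X[:, :, None]
        for lstm in self.lstms:
            h = lstm.forward(h, cache)
        for conv in self.convs:
            h = conv.forward(h, cache)
        h, self._drop1 = self._dropout(h, self.config.dropout_rates[0], train, rng)
        h = self.pool.forward(h, cache)
        h, self._drop2 = self._dropout(h, self.config.dropout_rates[1], train, rng)
        flat = h.reshape(h.shape[0], -1)
        self._flat_shape = h.shape
        feat = flat
        for dense in self.denses[:-1]:
            feat = dense.forward(feat, cache)
        if upto == "features":
            return feat
        logits = self.denses[-1].forward(feat, cache)
        logits = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        return ez / ez.sum(axis=1, keepdims=True)

    @staticmethod
    def _dropout(h, rate, train, rng):
        if not train or rate <= 0:
            return h, None
        mask = (rng.random(h.shape) >= rate).astype(h.dtype) / (1.0 - rate)
        return h * mask, mask

    def _backward(self, dprobs):
        d, _g = self.denses[-1].backward(dprobs)
        grads = {f"layer{len(self._layers()) - 1}/{k}": v for k, v in _g.items()}
        for i in range(len(self.denses) - 2, -1, -1):
            d, _g = self.denses[i].backward(d)
            li = len(self.lstms) + len(self.convs) + i
            grads.update({f"layer{li}/{k}": v for k, v in _g.items()})
        d = d.reshape(self._flat_shape)
        if self._drop2 is not None:
            d = d * self._drop2
        d = self.pool.backward(d)
        if self._drop1 is not None:
            d = d * self._drop1
        for i in range(len(self.convs) - 1, -1, -1):
            d, _g = self.convs[i].backward(d)
            li = len(self.lstms) + i
            grads.update({f"layer{li}/{k}": v for k, v in _g.items()})
        for i in range(len(self.lstms) - 1, -1, -1):
            d, _g = self.lstms[i].backward(d)
            grads.update({f"layer{i}/{k}": v for k, v in _g.items()})
        return grads

    # -- public API ---------------------------------------------------------

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        X = self._check_input(X)
        out = [
            self._forward(X[i: i + batch_size], train=False)
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.vstack(out).astype(float)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def features(self, X, batch_size: int = 256) -> np.ndarray:
        """Post-ReLU activations of the 128-unit dense layer (inference mode)."""
        X = self._check_input(X)
        out = [
            self._forward(X[i: i + batch_size], train=False, upto="features")
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.vstack(out).astype(float)

    def output_layer(self) -> tuple[np.ndarray, np.ndarray]:
        """Weights and bias of the final softmax dense layer."""
        last = self.denses[-1]
        return np.asarray(last.W, dtype=float), np.asarray(last.b, dtype=float)

    def fit(self, X, y, spec: TrainSpec | None = None) -> dict[str, list[float]]:
        spec = spec or TrainSpec()
        X = self._check_input(X)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise InvalidInputError("labels must align with beat rows")
        classes = np.unique(y)
        if classes.size < 2:
            raise InvalidInputError("training requires at least 2 classes")
        if y.min() < 0 or y.max() >= self.config.n_classes:
            raise InvalidInputError("labels outside [0, n_classes)")
        n = X.shape[0]
        onehot = np.zeros((n, self.config.n_classes), dtype=self.dtype)
        onehot[np.arange(n), y] = 1.0

        rng = np.random.default_rng(spec.seed)
        state = _AdamState(self.parameters(), spec.learning_rate)
        history = {"loss": [], "accuracy": []}
        for _epoch in range(spec.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                sel = order[start: start + spec.batch_size]
                xb, yb = X[sel], onehot[sel]
                probs = self._forward(xb, train=True, rng=rng)
                eps = 1e-12
                losses.append(float(-(yb * np.log(probs + eps)).sum() / sel.size))
                grads = self._backward((probs - yb) / sel.size)
                state.step(self.parameters(), grads)
            acc = float((self.predict(X) == y).mean())
            history["loss"].append(float(np.mean(losses)))
            history["accuracy"].append(acc)
        self.trained = True
        self.history = history
        return history

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        params = {k.replace("/", "__"): v for k, v in self.parameters().items()}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.config.__dict__, default=list).encode(), dtype=np.uint8
            ),
            __dtype__=np.frombuffer(self.dtype.name.encode(), dtype=np.uint8),
            **params,
        )

    @classmethod
    def load(cls, path) -> "CRNN":
        with np.load(path) as data:
            raw = json.loads(bytes(data["__config__"]).decode())
            for key in ("lstm_units", "dropout_rates", "dense_units"):
                raw[key] = tuple(raw[key])
            raw["conv_specs"] = tuple(tuple(p) for p in raw["conv_specs"])
            dtype = bytes(data["__dtype__"]).decode()
            net = cls(CRNNConfig(**raw), dtype=dtype)
            for k, arr in net.parameters().items():
                arr[...] = data[k.replace("/", "__")]
        net.trained = True
        return net


class _AdamState:
    def __init__(self, params: dict[str, np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def build_crnn(config: CRNNConfig, dtype=np.float32) -> CRNN:
    """Instantiate the network with seed-deterministic initial weights."""
    return CRNN(config, dtype=dtype)


def train_crnn(network: CRNN, beats, labels, spec: TrainSpec | None = None):
    """Train in place; returns ``(network, history)``."""
    history = network.fit(np.asarray(beats, dtype=float), labels, spec)
    return network, history


def extract_deep_features(network: CRNN, beats) -> np.ndarray:
    """n x 128 matrix of deep features (128-unit dense layer activations)."""
    if not network.trained:
        raise InvalidStateError("network must be trained before feature extraction")
    return network.features(np.asarray(beats, dtype=float))
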