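"""Per-timestep stacked recurrent sequence classifier, implemented in numpy.

Architecture: L stacked LSTM layers (the first with ``units_per_layer``
units, subsequent layers halved down to a floor of 32), each followed by
batch normalization and dropout; then a time-distributed ReLU dense layer
and a time-distributed softmax head, so the model emits class probabilities
at every one of the ten time steps rather than a single label per sequence.

Training uses Adam on class-weighted categorical cross-entropy with padded
steps masked out of the loss, a reduce-on-plateau learning-rate schedule and
early stopping on validation loss.  Everything is seeded, so a fixed seed
reproduces the run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ClassWeights, SequenceDataset

_RANGES = {
    "n_recurrent_layers": (1, 3),
    "units_per_layer": (64, 256),
    "dropout": (0.2, 0.5),
    "dense_units": (32, 128),
    "batch_size": (32, 128),
}

MIN_RECURRENT_UNITS = 32


@dataclass
class HyperParams:
    """Tunable model configuration; every field is validated against the
    search-space ranges the optimizer explores."""

    n_recurrent_layers: int = 2
    units_per_layer: int = 128
    dropout: float = 0.3
    dense_units: int = 64
    batch_size: int = 32
    learning_rate: float = 0.001

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ModelSpec:
    """Ordered layer descriptors plus the softmax head."""

    layers: list[tuple]  # ("lstm", units) | ("batchnorm",) | ("dropout", p) | ("dense", units, "relu")
    n_classes: int
    steps: int
    n_features: int
    learning_rate: float = 0.001
    batch_size: int = 32


def build_model(hp: HyperParams, steps: int, n_features: int, n_classes: int) -> ModelSpec:
    """Expand hyperparameters into the layer stack.

    With the default configuration (2 layers, 128 units, 64 dense) the stack
    before the softmax head is: lstm(128), batchnorm, dropout, lstm(64),
    batchnorm, dropout, dense(64, relu) — seven descriptors.
    """
    layers: list[tuple] = []
    units = hp.units_per_layer
    for _ in range(hp.n_recurrent_layers):
        layers.append(("lstm", int(units)))
        layers.append(("batchnorm",))
        layers.append(("dropout", float(hp.dropout)))
        units = max(MIN_RECURRENT_UNITS, units // 2)
    layers.append(("dense", int(hp.dense_units), "relu"))
    return ModelSpec(
        layers=layers,
        n_classes=n_classes,
        steps=steps,
        n_features=n_features,
        learning_rate=hp.learning_rate,
        batch_size=hp.batch_size,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class _LSTMLayer:
    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        h = units
        s_x = np.sqrt(6.0 / (d_in + 4 * h))
        s_h = np.sqrt(6.0 / (h + 4 * h))
        self.Wx = rng.uniform(-s_x, s_x, (d_in, 4 * h))
        self.Wh = rng.uniform(-s_h, s_h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.units = h

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray):
        n, t, _ = x.shape
        h = self.units
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        hs = np.zeros((n, t, h))
        cache = []
        for k in range(t):
            z = x[:, k] @ self.Wx + h_t @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            h_new = o * np.tanh(c_new)
            cache.append((x[:, k], h_t, c_t, i, f, g, o, c_new))
            h_t, c_t = h_new, c_new
            hs[:, k] = h_new
        return hs, cache

    def backward(self, dhs: np.ndarray, cache):
        n, t, h = dhs.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros((n, t, self.Wx.shape[0]))
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for k in reversed(range(t)):
            x_k, h_prev, c_prev, i, f, g, o, c = cache[k]
            dh = dhs[:, k] + dh_next
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc_next + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            dWx += x_k.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, k] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dx, [dWx, dWh, db]


class _BatchNormLayer:
    def __init__(self, d: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.run_mean = np.zeros(d)
        self.run_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool):
        n, t, d = x.shape
        flat = x.reshape(-1, d)
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean) * inv
        out = (self.gamma * xhat + self.beta).reshape(n, t, d)
        return out, (xhat, inv, (n, t, d))

    def backward(self, dout: np.ndarray, cache):
        xhat, inv, (n, t, d) = cache
        dflat = dout.reshape(-1, d)
        m = dflat.shape[0]
        dgamma = (dflat * xhat).sum(axis=0)
        dbeta = dflat.sum(axis=0)
        dxhat = dflat * self.gamma
        dx = inv / m * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        return dx.reshape(n, t, d), [dgamma, dbeta]


class _DenseLayer:
    def __init__(self, d_in: int, units: int, activation: str, rng: np.random.Generator):
        s = np.sqrt(6.0 / (d_in + units))
        self.W = rng.uniform(-s, s, (d_in, units))
        self.b = np.zeros(units)
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        z = x @ self.W + self.b
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        else:  # linear pre-softmax
            out = z
        return out, (x, z)

    def backward(self, dout: np.ndarray, cache):
        x, z = cache
        if self.activation == "relu":
            dout = dout * (z > 0)
        d = x.shape[-1]
        dW = x.reshape(-1, d).T @ dout.reshape(-1, dout.shape[-1])
        db = dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        dx = dout @ self.W.T
        return dx, [dW, db]


class SequenceClassifier:
    """A trainable instance of a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._layers: list = []
        d = spec.n_features
        for desc in spec.layers:
            if desc[0] == "lstm":
                self._layers.append(_LSTMLayer(d, desc[1], rng))
                d = desc[1]
            elif desc[0] == "batchnorm":
                self._layers.append(_BatchNormLayer(d))
            elif desc[0] == "dropout":
                self._layers.append(("dropout", desc[1]))
            elif desc[0] == "dense":
                self._layers.append(_DenseLayer(d, desc[1], desc[2], rng))
                d = desc[1]
        self._head = _DenseLayer(d, spec.n_classes, "linear", rng)

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers:
            if not isinstance(layer, tuple):
                out.extend(layer.params())
        out.extend(self._head.params())
        return out

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        caches = []
        for layer in self._layers:
            if isinstance(layer, tuple):  # dropout
                p = layer[1]
                if training and p > 0 and rng is not None:
                    keep = (rng.random(x.shape) >= p) / (1 - p)
                    x = x * keep
                    caches.append(("dropout", keep))
                else:
                    caches.append(("dropout", None))
            elif isinstance(layer, _BatchNormLayer):
                x, c = layer.forward(x, training)
                caches.append(("bn", c))
            else:
                x, c = layer.forward(x)
                caches.append(("layer", c))
        logits, head_cache = self._head.forward(x)
        return logits, caches, head_cache

    def _backward(self, dlogits: np.ndarray, caches, head_cache):
        grads: list[np.ndarray] = []
        dx, head_grads = self._head.backward(dlogits, head_cache)
        for layer, (kind, cache) in zip(reversed(self._layers), reversed(caches)):
            if kind == "dropout":
                if cache is not None:
                    dx = dx * cache
                continue
            if kind == "bn":
                dx, g = layer.backward(dx, cache)
            else:
                dx, g = layer.backward(dx, cache)
            grads = g + grads
        return grads + head_grads

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        """[n x steps x n_classes] softmax probabilities (inference mode)."""
        x = np.asarray(inputs, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.spec.steps or x.shape[2] != self.spec.n_features:
            raise ValueError(
                f"expected inputs [n x {self.spec.steps} x {self.spec.n_features}], got {x.shape}"
            )
        logits, _, _ = self._forward(x, training=False, rng=None)
        return _softmax(logits)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _weighted_loss(
    probs: np.ndarray, targets: np.ndarray, mask: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Masked class-weighted cross-entropy, mean over unpadded steps.

    Returns (loss, dlogits).  Because mean(w over samples) = 1 under
    inverse-frequency weights, a uniform predictor's loss is log(K)
    regardless of imbalance.
    """
    n, t, k = probs.shape
    valid = ~mask
    count = int(valid.sum())
    onehot = np.eye(k)[targets]
    p_true = np.clip((probs * onehot).sum(axis=-1), 1e-12, None)
    sample_w = w[targets] * valid
    loss = float((sample_w * -np.log(p_true)).sum() / count)
    dlogits = (probs - onehot) * sample_w[..., None] / count
    return loss, dlogits


def train_model(
    spec: ModelSpec,
    data: SequenceDataset,
    weights: ClassWeights | None = None,
    epochs: int = 50,
    seed: int = 0,
    val_data: SequenceDataset | None = None,
    val_fraction: float = 0.2,
    lr_factor: float = 0.5,
    lr_patience: int = 3,
    min_lr: float = 1e-5,
    early_stop_patience: int = 10,
) -> tuple[SequenceClassifier, dict[str, list[float]]]:
    """Fit the classifier; returns (model, history).

    History records per-epoch train loss, validation loss, learning rate and
    training accuracy.  The learning rate halves after ``lr_patience`` epochs
    without validation improvement (floor ``min_lr``); training stops early
    after ``early_stop_patience`` stale epochs.  A NaN loss aborts with
    diagnostics rather than training on.
    """
    model = SequenceClassifier(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)

    if weights is None:
        w = np.ones(data.n_classes)
    else:
        by_name = weights.as_dict()
        w = np.array([by_name.get(c, 1.0) for c in data.class_names])

    if val_data is None and val_fraction > 0 and len(data.inputs) >= 5:
        n_val = max(1, int(round(val_fraction * len(data.inputs))))
        order = rng.permutation(len(data.inputs))
        val_idx, train_idx = order[:n_val], order[n_val:]
    else:
        train_idx = np.arange(len(data.inputs))
        val_idx = None

    X, Y, M = data.inputs[train_idx], data.targets[train_idx], data.pad_mask[train_idx]
    if val_data is not None:
        Xv, Yv, Mv = val_data.inputs, val_data.targets, val_data.pad_mask
    elif val_idx is not None:
        Xv, Yv, Mv = data.inputs[val_idx], data.targets[val_idx], data.pad_mask[val_idx]
    else:
        Xv = None

    opt = _Adam(model.parameters(), spec.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "val_loss": [], "lr": [], "accuracy": []}
    best_val = np.inf
    stale = 0
    batch = spec.batch_size

    for _epoch in range(epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        n_batches = 0
        correct = 0
        total = 0
        for start in range(0, len(X), batch):
            idx = order[start : start + batch]
            xb, yb, mb = X[idx], Y[idx], M[idx]
            logits, caches, head_cache = model._forward(xb, training=True, rng=rng)
            probs = _softmax(logits)
            loss, dlogits = _weighted_loss(probs, yb, mb, w)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {_epoch}: lr={opt.lr}, batch={start // batch}"
                )
            grads = model._backward(dlogits, caches, head_cache)
            _clip_global_norm(grads, 5.0)
            opt.step(model.parameters(), grads)
            epoch_loss += loss
            n_batches += 1
            pred = probs.argmax(axis=-1)
            correct += int(((pred == yb) & ~mb).sum())
            total += int((~mb).sum())

        history["loss"].append(epoch_loss / max(n_batches, 1))
        history["accuracy"].append(correct / max(total, 1))
        history["lr"].append(opt.lr)

        if Xv is not None:
            probs_v = model.predict_proba(Xv)
            val_loss, _ = _weighted_loss(probs_v, Yv, Mv, w)
        else:
            val_loss = history["loss"][-1]
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale % lr_patience == 0:
                opt.lr = max(min_lr, opt.lr * lr_factor)
            if stale >= early_stop_patience:
                break
    return model, history


def _clip_global_norm(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale


def predict_proba(model: SequenceClassifier, inputs: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`SequenceClassifier.predict_proba`."""
    return model.predict_proba(inputs)
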