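"""The patch classifier: conv/relu/max-pool rounds followed by fully
connected layers, trained with backpropagation.

The network consumes a square patch whose side equals its receptive field
and emits one score per class (background / boundary / interior, plus an
optional second interior class for co-culture semantic segmentation).  The
architecture is the classic small conv-net: several rounds of convolution
(3-5 px filters), a relu transfer function, optional 2x2/stride-2
max-pooling, then a fully connected head; training minimizes the soft-max
(cross-entropy) cost with an L2 penalty on the convolution filter weights,
by mini-batch gradient descent (plain SGD or RMSprop).

Everything here is plain NumPy: forward passes are im2col matrix products,
gradients are written out analytically, and `dense_scores` evaluates the
same weights fully convolutionally with d-regularly-sparse (dilated)
kernels so that whole-image inference is exactly equivalent to sliding the
patch classifier over every pixel.

The training interface follows the model/results idiom: a
:class:`PatchClassifier` is built from a :class:`~cellsegnet.data.PatchDataset`
and a :class:`NetworkSpec`; its :meth:`~PatchClassifier.fit` returns a
:class:`TrainingResults` holding the weights, the per-epoch train/validation
error log, and a ``summary()``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConvRound",
    "NetworkSpec",
    "TrainConfig",
    "receptive_field",
    "softmax",
    "cost",
    "PatchClassifier",
    "TrainingResults",
    "train_ensemble",
    "load_checkpoint",
    "TEST_FAMILY",
    "FULL_FAMILY",
]


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class ConvRound:
    """One dimensionality-reduction round: convolution with ``n_filters``
    square filters of side ``filter_size`` (3-5 px), relu, and optional
    2x2/stride-2 max-pooling."""

    filter_size: int
    n_filters: int
    maxpool: bool = False


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of a patch classifier.

    ``fc_widths`` are the hidden fully connected widths; a final class-score
    layer of width ``n_classes`` is always appended, so the fully connected
    depth q equals ``len(fc_widths) + 1``.
    """

    conv_rounds: tuple[ConvRound, ...]
    fc_widths: tuple[int, ...] = (64,)
    n_classes: int = 3
    input_channels: int = 1
    batch_norm: bool = True
    dropout_fc: float = 0.0

    def __post_init__(self) -> None:
        for r in self.conv_rounds:
            if r.filter_size not in (3, 4, 5):
                raise ValueError("filter sizes are 3-5 px")
        if self.n_classes not in (2, 3, 4):
            raise ValueError("n_classes must be 2, 3 or 4")
        if not 0 <= self.dropout_fc < 1:
            raise ValueError("dropout_fc must be in [0, 1)")
        # the conv stack must reduce a receptive-field patch to exactly 1x1,
        # with every max-pool seeing an even input
        s = receptive_field(self)
        for r in self.conv_rounds:
            s -= r.filter_size - 1
            if r.maxpool:
                if s % 2:
                    raise ValueError(
                        "max-pool input size is odd; adjust filter sizes"
                    )
                s //= 2
        assert s == 1

    @property
    def fc_depth(self) -> int:
        return len(self.fc_widths) + 1

    def to_json(self) -> str:
        d = asdict(self)
        d["conv_rounds"] = [asdict(r) for r in self.conv_rounds]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        d["conv_rounds"] = tuple(ConvRound(**r) for r in d["conv_rounds"])
        d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)


def receptive_field(spec: NetworkSpec) -> int:
    """Side length of the input region influencing one classifier output;
    equals the patch size the network must be trained on.  Computed by
    inverting the conv/pool size arithmetic from a 1x1 output."""
    s = 1
    for r in reversed(spec.conv_rounds):
        if r.maxpool:
            s *= 2
        s += r.filter_size - 1
    return s


#: small architectures for desk-scale experiments, keyed by receptive field
TEST_FAMILY = {
    9: NetworkSpec(
        conv_rounds=(ConvRound(4, 8, True), ConvRound(3, 8)),
        fc_widths=(16,),
    ),
    13: NetworkSpec(
        conv_rounds=(ConvRound(4, 8, True), ConvRound(5, 16)),
        fc_widths=(32,),
    ),
    21: NetworkSpec(
        conv_rounds=(ConvRound(4, 8, True), ConvRound(4, 16, True), ConvRound(3, 16)),
        fc_widths=(48,),
    ),
    31: NetworkSpec(
        conv_rounds=(ConvRound(4, 8, True), ConvRound(5, 16, True), ConvRound(5, 16)),
        fc_widths=(64,),
    ),
}

#: full-scale family (4-6 conv rounds); per-layer counts are configurable,
#: these defaults use 64 filters throughout
FULL_FAMILY = {
    31: NetworkSpec(
        conv_rounds=(
            ConvRound(4, 64, True), ConvRound(3, 64, True),
            ConvRound(3, 64), ConvRound(4, 64),
        ),
        fc_widths=(200, 200),
    ),
    61: NetworkSpec(
        conv_rounds=(
            ConvRound(4, 64, True), ConvRound(4, 64, True),
            ConvRound(4, 64, True), ConvRound(5, 64),
        ),
        fc_widths=(200, 200),
    ),
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for :meth:`PatchClassifier.fit`."""

    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    l2_lambda: float = 1e-5
    batch_size: int = 256
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "rmsprop"):
            raise ValueError("optimizer must be 'sgd' or 'rmsprop'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


# ---------------------------------------------------------------------------
# layers

class _Conv:
    kind = "conv"

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.dW = self.db = None
        self._cache = None

    def forward(self, x, train):
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        cols = sliding_window_view(x, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * ho * wo, c * k * k)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T + self.b
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k = self.k
        f = self.W.shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dW = (dmat.T @ cols).reshape(self.W.shape)
        self.db = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(f, -1)).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(xshape)
        for a in range(k):
            for b in range(k):
                dx[:, :, a : a + ho, b : b + wo] += dcols[:, :, :, :, a, b]
        self._cache = None
        return dx

    def dense(self, x, d):
        """Dilated valid convolution for whole-image inference."""
        c, h, w = x.shape
        k = self.k
        ho, wo = h - (k - 1) * d, w - (k - 1) * d
        out = np.empty((self.W.shape[0], ho, wo))
        out[:] = self.b[:, None, None]
        for a in range(k):
            for b in range(k):
                out += np.tensordot(
                    self.W[:, :, a, b],
                    x[:, a * d : a * d + ho, b * d : b * d + wo],
                    axes=([1], [0]),
                )
        return out, d

    def params(self):
        return [("W", True), ("b", False)]


class _BatchNorm:
    """Per-channel batch normalization over batch and spatial axes."""

    kind = "batchnorm"
    momentum = 0.9
    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.dgamma = self.dbeta = None
        self._cache = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[:, None, None]
        dxhat = dout * g
        dx = (inv[:, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )
        self._cache = None
        return dx

    def dense(self, x, d):
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (
            self.gamma[:, None, None] * (x - self.running_mean[:, None, None]) * inv[:, None, None]
            + self.beta[:, None, None]
        ), d

    def params(self):
        return [("gamma", False), ("beta", False)]


class _ReLU:
    kind = "relu"

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask

    def dense(self, x, d):
        return np.maximum(x, 0.0), d

    def params(self):
        return []


class _MaxPool:
    """2x2 window, stride 2."""

    kind = "maxpool"

    def forward(self, x, train):
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (n, c, h, w) = self._cache
        dwin = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(n, c, h, w)

    def dense(self, x, d):
        """Dense equivalent: max over a 2x2 window dilated by d, stride 1;
        subsequent layers then use dilation 2d."""
        c, h, w = x.shape
        ho, wo = h - d, w - d
        out = np.maximum(
            np.maximum(x[:, :ho, :wo], x[:, :ho, d:]),
            np.maximum(x[:, d:, :wo], x[:, d:, d:]),
        )
        return out, 2 * d

    def params(self):
        return []


class _Flatten:
    kind = "flatten"

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def dense(self, x, d):
        return x, d  # conv output is 1x1 per position; channels carry through

    def params(self):
        return []


class _Dense:
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = self.db = None

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        dx = dout @ self.W
        self._x = None
        return dx

    def dense(self, x, d):
        return np.tensordot(self.W, x, axes=([1], [0])) + self.b[:, None, None], d

    def params(self):
        return [("W", False), ("b", False)]


class _Dropout:
    kind = "dropout"

    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def dense(self, x, d):
        return x, d

    def params(self):
        return []


# ---------------------------------------------------------------------------
# network

class Network:
    """Layer stack instantiated from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers: list = []
        ch = spec.input_channels
        for r in spec.conv_rounds:
            self.layers.append(_Conv(ch, r.n_filters, r.filter_size, rng))
            if spec.batch_norm:
                self.layers.append(_BatchNorm(r.n_filters))
            self.layers.append(_ReLU())
            if r.maxpool:
                self.layers.append(_MaxPool())
            ch = r.n_filters
        self.layers.append(_Flatten())
        n_in = ch  # conv output is 1x1 x ch at the receptive-field patch size
        for width in spec.fc_widths:
            self.layers.append(_Dense(n_in, width, rng))
            self.layers.append(_ReLU())
            if spec.dropout_fc > 0:
                self.layers.append(_Dropout(spec.dropout_fc))
            n_in = width
        self.layers.append(_Dense(n_in, spec.n_classes, rng))

    # -- patch mode -----------------------------------------------------
    def forward(self, patches: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class scores for a batch of patches (n, channels, p, p) or a
        single patch (channels, p, p)."""
        x = np.asarray(patches, dtype=float)
        single = x.ndim == 3
        if single:
            x = x[None]
        p = receptive_field(self.spec)
        if x.shape[1] != self.spec.input_channels or x.shape[2:] != (p, p):
            raise ValueError(
                f"expected patches of shape ({self.spec.input_channels}, {p}, {p}),"
                f" got {x.shape[1:]}"
            )
        for layer in self.layers:
            if layer.kind == "dropout":
                layer.rng = rng
            x = layer.forward(x, train)
        return x[0] if single else x

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        g = dscores
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    # -- dense (fully convolutional) mode -------------------------------
    def dense_scores(self, pixels: np.ndarray) -> np.ndarray:
        """Evaluate the classifier at every position of a (channels, H, W)
        image using dilated kernels; returns raw scores of shape
        (n_classes, H - rf + 1, W - rf + 1), identical (up to float error)
        to running ``forward`` on every extractable patch."""
        x = np.asarray(pixels, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[0] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} channels, got {x.shape[0]}"
            )
        d = 1
        for layer in self.layers:
            x, d = layer.dense(x, d)
        return x

    # -- parameters ------------------------------------------------------
    def param_arrays(self):
        """Yield (layer, attr_name, is_conv_filter) for every parameter."""
        for layer in self.layers:
            for name, is_filter in layer.params():
                yield layer, name, is_filter

    def conv_filter_weights(self):
        return [l.W for l in self.layers if l.kind == "conv"]

    def filter_weight_sq_sum(self) -> float:
        return float(sum((w ** 2).sum() for w in self.conv_filter_weights()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, _ in layer.params():
                out[f"{i}:{name}"] = getattr(layer, name)
            if layer.kind == "batchnorm":
                out[f"{i}:running_mean"] = layer.running_mean
                out[f"{i}:running_var"] = layer.running_var
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, value in arrays.items():
            idx, name = key.split(":")
            setattr(self.layers[int(idx)], name, np.array(value))


def softmax(scores: np.ndarray) -> np.ndarray:
    """Soft-max normalized scores e^s / sum e^s along the last axis."""
    s = scores - np.max(scores, axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def cost(scores: np.ndarray, labels: np.ndarray, network: Network | None = None,
         l2_lambda: float = 0.0) -> float:
    """Soft-max cost: negative log likelihood of the correct class, summed
    over the batch, plus l2_lambda times the sum of squared convolution
    filter weights."""
    scores = np.atleast_2d(scores)
    labels = np.atleast_1d(labels)
    p = softmax(scores)
    nll = -np.log(np.clip(p[np.arange(len(labels)), labels], 1e-300, None)).sum()
    reg = l2_lambda * network.filter_weight_sq_sum() if network is not None else 0.0
    return float(nll + reg)


def _cost_grad(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(summed nll)/d(scores)."""
    p = softmax(scores)
    p[np.arange(len(labels)), labels] -= 1.0
    return p


# ---------------------------------------------------------------------------
# optimizers

class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, param, grad, key):
        param -= self.lr * grad


class _RMSprop:
    decay = 0.9
    eps = 1e-8

    def __init__(self, lr):
        self.lr = lr
        self.cache: dict = {}

    def step(self, param, grad, key):
        c = self.cache.get(key)
        if c is None:
            c = np.zeros_like(param)
        c = self.decay * c + (1 - self.decay) * grad ** 2
        self.cache[key] = c
        param -= self.lr * grad / (np.sqrt(c) + self.eps)


# ---------------------------------------------------------------------------
# model / results

class PatchClassifier:
    """Patch-classification model: a dataset plus an architecture.

    Parameters
    ----------
    dataset : PatchDataset
        Balanced training patches; ``dataset.patch_size`` must equal the
        spec's receptive field.
    spec : NetworkSpec
        Architecture to train.
    """

    def __init__(self, dataset, spec: NetworkSpec):
        if dataset.patch_size != receptive_field(spec):
            raise ValueError(
                f"dataset patch size {dataset.patch_size} != receptive field "
                f"{receptive_field(spec)}"
            )
        if dataset.input_channels != spec.input_channels:
            raise ValueError("dataset channel count does not match spec")
        if dataset.n_classes != spec.n_classes:
            raise ValueError("dataset class count does not match spec")
        self.dataset = dataset
        self.spec = spec

    def fit(self, config: TrainConfig | None = None) -> "TrainingResults":
        """Train by mini-batch gradient descent with on-the-fly dihedral
        augmentation; the (stratified, seeded) 10% validation split of the
        dataset is scored after every epoch.  Deterministic for a fixed
        seed in single-threaded execution."""
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        net = Network(self.spec, rng)
        opt = (_RMSprop if config.optimizer == "rmsprop" else _SGD)(
            config.learning_rate
        )
        history = []
        for epoch in range(config.epochs):
            n_seen = n_wrong = 0
            cost_sum = 0.0
            for X, y in self.dataset.training_batches(config.batch_size, rng):
                scores = net.forward(X, train=True, rng=rng)
                batch_cost = cost(scores, y, net, config.l2_lambda)
                if not np.isfinite(batch_cost):
                    raise FloatingPointError(
                        f"training diverged (cost={batch_cost}) at epoch {epoch}"
                    )
                cost_sum += batch_cost
                n_wrong += int((scores.argmax(axis=1) != y).sum())
                n_seen += len(y)
                dscores = _cost_grad(scores, y) / len(y)
                net.backward(dscores)
                for i, (layer, name, is_filter) in enumerate(net.param_arrays()):
                    grad = getattr(layer, "d" + name)
                    if is_filter and config.l2_lambda > 0:
                        grad = grad + 2.0 * config.l2_lambda * getattr(layer, name)
                    opt.step(getattr(layer, name), grad, i)
            val_err = _classification_error(net, self.dataset.validation_set())
            history.append(
                {
                    "epoch": epoch,
                    "train_err": n_wrong / max(n_seen, 1),
                    "val_err": val_err,
                    "cost": cost_sum / max(n_seen, 1),
                }
            )
        return TrainingResults(network=net, spec=self.spec, config=config,
                               history=history)


def _classification_error(net: Network, batches) -> float:
    wrong = total = 0
    for X, y in batches:
        scores = net.forward(X)
        wrong += int((scores.argmax(axis=1) != y).sum())
        total += len(y)
    return wrong / max(total, 1)


@dataclass
class TrainingResults:
    """Trained weights plus the training log.

    ``history`` is a list of per-epoch dicts (epoch, train_err, val_err,
    cost); ``history_frame()`` returns it as a DataFrame, and
    ``save``/``load_checkpoint`` round-trip the weights bit-exactly.
    """

    network: Network
    spec: NetworkSpec
    config: TrainConfig
    history: list = field(default_factory=list)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return softmax(self.network.forward(patches))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.network.forward(patches).argmax(axis=-1)

    @property
    def final_validation_error(self) -> float:
        return self.history[-1]["val_err"] if self.history else float("nan")

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def history_csv(self, path: str | Path) -> None:
        self.history_frame().to_csv(path, index=False)

    def summary(self) -> str:
        rf = receptive_field(self.spec)
        lines = [
            "Patch classifier training results",
            "=================================",
            f"receptive field:      {rf} px",
            f"conv rounds:          {len(self.spec.conv_rounds)}"
            f" {[ (r.filter_size, r.n_filters, r.maxpool) for r in self.spec.conv_rounds]}",
            f"fully connected:      q={self.spec.fc_depth}, widths {self.spec.fc_widths}",
            f"classes:              {self.spec.n_classes}",
            f"batch norm / dropout: {self.spec.batch_norm} / {self.spec.dropout_fc}",
            f"optimizer:            {self.config.optimizer}"
            f" (lr={self.config.learning_rate}, lambda={self.config.l2_lambda})",
            f"epochs:               {len(self.history)}",
        ]
        if self.history:
            h = self.history[-1]
            lines.append(
                f"final errors:         train {h['train_err']:.4f}, "
                f"validation {h['val_err']:.4f}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: spec + config JSON and weight arrays."""
        arrays = self.network.state_arrays()
        meta = {
            "spec": json.loads(self.spec.to_json()),
            "config": asdict(self.config),
            "history": self.history,
        }
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainingResults:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    spec = NetworkSpec.from_json(json.dumps(meta["spec"]))
    config = TrainConfig(**meta["config"])
    net = Network(spec, np.random.default_rng(0))
    net.load_state(arrays)
    return TrainingResults(network=net, spec=spec, config=config,
                           history=meta["history"])


def train_ensemble(dataset, spec: NetworkSpec, config: TrainConfig,
                   n_models: int = 5) -> list[TrainingResults]:
    """Train ``n_models`` networks from distinct random initializations
    (seeds config.seed, config.seed+1, ...); their score maps are averaged
    at inference time (model parallelism).  Default ensemble size 5."""
    out = []
    for i in range(n_models):
        cfg = TrainConfig(**{**asdict(config), "seed": config.seed + i})
        out.append(PatchClassifier(dataset, spec).fit(cfg))
    return out
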