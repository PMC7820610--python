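"""3D convolutional feature extractor and parameter-regression training.

The backbone is a stack of conv -> batch-norm -> leaky-ReLU(0.1) blocks
interleaved with 3D max pooling, closed by global average pooling and one
fully connected layer; the regression head has 6 linear outputs (three
Euler angles, three translations) trained with the half-mean-squared-error
loss under SGD with momentum 0.9 and a step learning-rate schedule (0.001,
dropped to 0.0001 after epoch 20, 30 epochs, 30% of the data held out for
validation).  The last conv block always has 128 channels, so the global
average pool yields a 128-feature vector per image; the concatenated
(MRI, CT) pair vector of length 256 feeds the downstream regressor.

All layers are implemented directly on numpy arrays (forward and backward),
with convolution as a sliding-window tensor contraction.  Layout is
channels-first: (N, C, X, Y, Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import RegistrationParams
from .volume import Volume, resize_to_grid

# ---------------------------------------------------------------------------
# layers


class Param:
    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.velocity = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 (configurable) convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        k = kernel
        fan_in = c_in * k**3
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k)))
        self.b = Param(np.zeros(c_out))
        self.kernel = k

    def params(self):
        return [self.w, self.b]

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        k = self.kernel
        return np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))

    def forward(self, x, train):
        p = self.kernel // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = self._windows(self._xp)  # (N, C, X, Y, Z, k, k, k)
        out = np.tensordot(win, self.w.value, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        return np.moveaxis(out, -1, 1) + self.b.value[None, :, None, None, None]

    def backward(self, grad):
        win = self._windows(self._xp)
        self.w.grad = np.tensordot(grad, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.b.grad = grad.sum(axis=(0, 2, 3, 4))
        k = self.kernel
        N, _, Xp, Yp, Zp = self._xp.shape
        X, Y, Z = Xp - 2 * (k // 2), Yp - 2 * (k // 2), Zp - 2 * (k // 2)
        dxp = np.zeros_like(self._xp)
        for a in range(k):
            for b in range(k):
                for d in range(k):
                    dxp[:, :, a : a + X, b : b + Y, d : d + Z] += np.einsum(
                        "noxyz,oc->ncxyz", grad, self.w.value[:, :, a, b, d], optimize=True
                    )
        p = k // 2
        self._xp = None
        return dxp[:, :, p : Xp - p, p : Yp - p, p : Zp - p]


class BatchNorm3D(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None, None]
        self._xhat = (x - mean[None, :, None, None, None]) / self._std
        self._train = train
        return self.gamma.value[None, :, None, None, None] * self._xhat + self.beta.value[
            None, :, None, None, None
        ]

    def backward(self, grad):
        axes = (0, 2, 3, 4)
        self.gamma.grad = (grad * self._xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        if not self._train:
            return grad * g / self._std
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        dxhat = grad * g
        return (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        ) / self._std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x, train):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class MaxPool3D(Layer):
    def __init__(self, window: tuple[int, int, int]):
        self.window = tuple(int(w) for w in window)

    def forward(self, x, train):
        wx, wy, wz = self.window
        N, C, X, Y, Z = x.shape
        if X % wx or Y % wy or Z % wz:
            raise ValueError(f"dims {x.shape[2:]} not divisible by pool window {self.window}")
        r = x.reshape(N, C, X // wx, wx, Y // wy, wy, Z // wz, wz)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7)  # (N, C, Xb, Yb, Zb, wx, wy, wz)
        flat = r.reshape(N, C, X // wx, Y // wy, Z // wz, wx * wy * wz)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        wx, wy, wz = self.window
        N, C, X, Y, Z = self._in_shape
        flat = np.zeros((N, C, X // wx, Y // wy, Z // wz, wx * wy * wz))
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        r = flat.reshape(N, C, X // wx, Y // wy, Z // wz, wx, wy, wz)
        r = r.transpose(0, 1, 2, 5, 3, 6, 4, 7)  # interleave blocks back
        return r.reshape(N, C, X, Y, Z)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        nx, ny, nz = self._spatial
        return np.broadcast_to(
            grad[:, :, None, None, None] / (nx * ny * nz), grad.shape + self._spatial
        ).copy()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad = grad.T @ self._x
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value


# ---------------------------------------------------------------------------
# configuration and model


@dataclass(frozen=True)
class DCNNConfig:
    """Backbone architecture and training hyperparameters.

    The last conv block must have 128 channels (the feature-vector width);
    the learning rate is ``lr_initial`` through ``lr_drop_epoch`` epochs and
    ``lr_after_drop`` afterwards.
    """

    input_dims: tuple[int, int, int] = (32, 32, 8)
    conv_channels: tuple[int, ...] = (8, 16, 128)
    kernel_size: int = 3
    pool_windows: tuple = ((2, 2, 2), (2, 2, 2), None)
    leaky_slope: float = 0.1
    momentum: float = 0.9
    lr_initial: float = 0.001
    lr_after_drop: float = 0.0001
    lr_drop_epoch: int = 20
    max_epochs: int = 30
    validation_fraction: float = 0.30
    batch_size: int = 8
    n_outputs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_channels[-1] != 128:
            raise ValueError("the last conv block must have exactly 128 channels")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation fraction must be in (0, 1)")
        if len(self.pool_windows) != len(self.conv_channels):
            raise ValueError("need one pool window entry (or None) per conv block")
        dims = list(self.input_dims)
        for w in self.pool_windows:
            if w is None:
                continue
            for ax in range(3):
                if dims[ax] % w[ax] or dims[ax] // w[ax] < 1:
                    raise ValueError(
                        f"input dims {self.input_dims} too small for pooling chain "
                        f"{self.pool_windows}"
                    )
                dims[ax] //= w[ax]

    @classmethod
    def full_preset(cls, **overrides) -> "DCNNConfig":
        """Full-scale preset: 256 x 256 x 26 input, five conv blocks to 128."""
        base = dict(
            input_dims=(256, 256, 26),
            conv_channels=(8, 16, 32, 64, 128),
            pool_windows=((2, 2, 1), (2, 2, 2), (2, 2, 1), (2, 2, 1), None),
        )
        base.update(overrides)
        return cls(**base)


class SequentialModel:
    """A feed-forward stack with an explicit feature tap at the global pool."""

    def __init__(self, layers: list[Layer], feature_index: int, cfg: DCNNConfig):
        self.layers = layers
        self.feature_index = feature_index  # index of the GlobalAvgPool layer
        self.cfg = cfg
        self.trained = False

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def features(self, x: np.ndarray) -> np.ndarray:
        """Global-average-pooled last-conv activations (inference mode)."""
        for layer in self.layers[: self.feature_index + 1]:
            x = layer.forward(x, train=False)
        return x


def build_dcnn(cfg: DCNNConfig | None = None) -> SequentialModel:
    """Conv/BN/leaky-ReLU blocks + max pools + GAP + one dense head."""
    cfg = cfg or DCNNConfig()
    rng = np.random.default_rng(cfg.seed)
    layers: list[Layer] = []
    c_prev = 1
    for ch, pool in zip(cfg.conv_channels, cfg.pool_windows):
        layers.append(Conv3D(c_prev, ch, cfg.kernel_size, rng))
        layers.append(BatchNorm3D(ch))
        layers.append(LeakyReLU(cfg.leaky_slope))
        if pool is not None:
            layers.append(MaxPool3D(pool))
        c_prev = ch
    feature_index = len(layers)
    layers.append(GlobalAvgPool())
    layers.append(Dense(c_prev, cfg.n_outputs, rng))
    return SequentialModel(layers, feature_index, cfg)


# ---------------------------------------------------------------------------
# losses


def half_mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Half mean squared error over the k outputs: (1/2k) sum (pred-target)^2.

    For a batch the per-sample losses are averaged.
    """
    pred = np.atleast_2d(np.asarray(pred, float))
    target = np.atleast_2d(np.asarray(target, float))
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    k = pred.shape[1]
    return float(np.mean(np.sum((pred - target) ** 2, axis=1) / (2 * k)))


def _half_mse_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    n, k = pred.shape
    return (pred - target) / (k * n)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    p = softmax(np.atleast_2d(logits))
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + 1e-300)))


def _cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    p = softmax(logits)
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)


_LOSSES = {
    "half_mse": (half_mse_loss, _half_mse_grad),
    "cross_entropy": (cross_entropy_loss, _cross_entropy_grad),
}


# ---------------------------------------------------------------------------
# training


def learning_rate_schedule(cfg: DCNNConfig) -> list[float]:
    """Per-epoch learning rates: lr_initial for the first ``lr_drop_epoch``
    epochs, lr_after_drop for the rest."""
    return [
        cfg.lr_initial if epoch <= cfg.lr_drop_epoch else cfg.lr_after_drop
        for epoch in range(1, cfg.max_epochs + 1)
    ]


def train_model(
    model: SequentialModel,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: DCNNConfig | None = None,
    loss: str = "half_mse",
) -> dict:
    """SGDM training loop shared by the regression and classification heads.

    ``inputs`` is (N, 1, X, Y, Z); ``targets`` is (N, k) for regression or
    (N,) integer labels for classification.  A fraction
    ``cfg.validation_fraction`` of the data (rounded) is held out for
    validation.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    if len(inputs) == 0:
        raise ValueError("empty training set")
    loss_fn, grad_fn = _LOSSES[loss]
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(inputs)
    n_val = int(round(cfg.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training samples left after the validation split")
    lrs = learning_rate_schedule(cfg)
    history = {"train_loss": [], "val_loss": [], "lr": [], "n_train": len(train_idx), "n_val": n_val}
    params = model.params()
    for epoch, lr in enumerate(lrs, start=1):
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            out = model.forward(inputs[sel], train=True)
            losses.append(loss_fn(out, targets[sel]))
            model.backward(grad_fn(out, targets[sel]))
            for p in params:
                p.velocity = cfg.momentum * p.velocity - lr * p.grad
                p.value = p.value + p.velocity
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            out = model.forward(inputs[val_idx], train=False)
            history["val_loss"].append(loss_fn(out, targets[val_idx]))
        else:
            history["val_loss"].append(float("nan"))
        history["lr"].append(lr)
    model.trained = True
    return history


def volume_to_input(v: Volume, cfg: DCNNConfig) -> np.ndarray:
    """Resize a volume to the network grid and add batch/channel axes."""
    if v.dims != tuple(cfg.input_dims):
        v = resize_to_grid(v, cfg.input_dims)
    return v.voxels[None, None, :, :, :]


def dataset_to_arrays(dataset, cfg: DCNNConfig, split: str | None = None):
    """(inputs, targets) arrays from a registration dataset.

    The network input is the moving image; the target is the 6-parameter
    truth vector on its natural scale (degrees / voxels).
    """
    records = dataset.subset(split) if split else list(dataset)
    if not records:
        raise ValueError(f"no records in split {split!r}")
    inputs = np.concatenate([volume_to_input(r.moving, cfg) for r in records], axis=0)
    targets = np.stack([r.truth.as_array() for r in records], axis=0)
    return inputs, targets


def train_dcnn(model: SequentialModel, dataset, cfg: DCNNConfig | None = None):
    """Train the regression backbone on a dataset's train split."""
    cfg = cfg or model.cfg
    inputs, targets = dataset_to_arrays(dataset, cfg, split="train")
    history = train_model(model, inputs, targets, cfg, loss="half_mse")
    return model, history


def extract_features(model: SequentialModel, v: Volume) -> np.ndarray:
    """128 global-average-pooled last-conv activations, inference mode."""
    return model.features(volume_to_input(v, model.cfg))[0]


def concat_pair_features(f_fixed: np.ndarray, f_moving: np.ndarray) -> np.ndarray:
    """Pair feature vector: fixed (MRI) features first, moving (CT) second."""
    f_fixed = np.asarray(f_fixed, float).ravel()
    f_moving = np.asarray(f_moving, float).ravel()
    if f_fixed.size != 128 or f_moving.size != 128:
        raise ValueError("each feature vector must have exactly 128 entries")
    return np.concatenate([f_fixed, f_moving])


def predict_params(model: SequentialModel, v: Volume) -> RegistrationParams:
    """End-to-end DCNN prediction of the 6 registration parameters."""
    out = model.forward(volume_to_input(v, model.cfg), train=False)[0]
    return RegistrationParams.from_array(out)


def r_squared(pred, truth) -> tuple[float, np.ndarray]:
    """Pooled and per-parameter coefficient of determination.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the per-output mean of the
    truth; the pooled value sums both over all outputs.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 2 or pred.shape[0] < 2:
        raise ValueError("need matching (n >= 2, k) prediction and truth arrays")
    ss_res = np.sum((pred - truth) ** 2, axis=0)
    ss_tot = np.sum((truth - truth.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        raise ValueError("zero variance in truth for at least one output")
    per_param = 1.0 - ss_res / ss_tot
    pooled = 1.0 - ss_res.sum() / ss_tot.sum()
    return float(pooled), per_param
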