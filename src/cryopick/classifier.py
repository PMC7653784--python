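"""Deep classification network for particle patches, implemented in numpy.

The full architecture is the 13-layer chain: input/preprocessing (227x227x3),
five convolutional layers (96@11x11 s4, 256@5x5 p2, 384@3x3 p1, 384@3x3 p1,
256@3x3 p1), three 3x3 s2 max-pooling layers, two 4096-unit fully connected
layers and a softmax output over 3-5 classes. Feature maps pass through a
sigmoid non-linearity; training minimizes summed cross-entropy with an L2
penalty by mini-batch stochastic gradient descent with the eta/N update rule,
gradients obtained by backpropagation.

A reduced preset (32x32 input, two conv blocks) provides the same operators at
desk scale for tests and synthetic end-to-end runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LayerSpec",
    "TrainingConfig",
    "TrainingState",
    "Network",
    "TABLE9_ARCH",
    "toy_arch",
    "spatial_size_chain",
    "build_network",
    "sigmoid",
    "conv_forward",
    "maxpool_forward",
    "softmax",
    "loss",
    "sgd_step",
    "train",
    "predict_patch",
    "save_model",
    "load_model",
]

LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the chain; unused fields stay at their defaults."""

    kind: str  # input | conv | maxpool | fully_connected | output
    n_filters: int = 0
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    out_units: int = 0
    channels: int = 0  # input layers only
    size: int = 0      # input layers only


# Strides/padding reproduce the printed feature-map chain
# 227 -> 55 -> 27 -> 27 -> 13 -> 13 -> 13 -> 13 -> 6.
TABLE9_ARCH: tuple[LayerSpec, ...] = (
    LayerSpec("input", size=227, channels=3),
    LayerSpec("conv", n_filters=96, kernel=11, stride=4, padding=0),
    LayerSpec("maxpool", kernel=3, stride=2),
    LayerSpec("conv", n_filters=256, kernel=5, stride=1, padding=2),
    LayerSpec("maxpool", kernel=3, stride=2),
    LayerSpec("conv", n_filters=384, kernel=3, stride=1, padding=1),
    LayerSpec("conv", n_filters=384, kernel=3, stride=1, padding=1),
    LayerSpec("conv", n_filters=256, kernel=3, stride=1, padding=1),
    LayerSpec("maxpool", kernel=3, stride=2),
    LayerSpec("fully_connected", out_units=4096),
    LayerSpec("fully_connected", out_units=4096),
    LayerSpec("output"),
)


def toy_arch(input_size: int = 32, channels: int = 1) -> tuple[LayerSpec, ...]:
    """Reduced two-conv-block preset for desk-scale training."""
    return (
        LayerSpec("input", size=input_size, channels=channels),
        LayerSpec("conv", n_filters=8, kernel=5, stride=1, padding=2),
        LayerSpec("maxpool", kernel=2, stride=2),
        LayerSpec("conv", n_filters=16, kernel=3, stride=1, padding=1),
        LayerSpec("maxpool", kernel=2, stride=2),
        LayerSpec("fully_connected", out_units=64),
        LayerSpec("output"),
    )


def spatial_size_chain(arch: tuple[LayerSpec, ...]) -> list[int]:
    """Output spatial size after every conv/pool layer.

    For the full preset this is [55, 27, 27, 13, 13, 13, 13, 6].
    """
    size = None
    chain: list[int] = []
    for spec in arch:
        if spec.kind == "input":
            size = spec.size
        elif spec.kind in ("conv", "maxpool"):
            if size is None:
                raise ValueError("architecture must start with an input layer")
            size = (size + 2 * spec.padding - spec.kernel) // spec.stride + 1
            if size < 1:
                raise ValueError(f"layer {spec} collapses the spatial size to {size}")
            chain.append(size)
    return chain


# ---------------------------------------------------------------------------
# elementary operators
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """1 / (1 + exp(-x)), numerically stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int
            ) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N, oh, ow, C*kh*kw) window matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"kernel {kh}x{kw} larger than padded input {x.shape[2:]}")
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3), writeable=False)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int, pad: int
            ) -> np.ndarray:
    """Adjoint of _im2col: scatter-add window gradients back to the input."""
    n, c, h, w = x_shape
    oh, ow = dcols.shape[1], dcols.shape[2]
    dpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, oh, ow, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dpad[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += \
                d6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dpad[:, :, pad:pad + h, pad:pad + w] if pad else dpad


def conv_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray,
                 stride: int = 1, padding: int = 0,
                 activation: str | None = "sigmoid") -> np.ndarray:
    """Shared-weight cross-correlation plus bias, then the activation.

    x: (N, C, H, W); weights: (F, C, kh, kw); bias: (F,).
    """
    f, c, kh, kw = weights.shape
    if x.shape[1] != c:
        raise ValueError(f"input has {x.shape[1]} channels, kernel expects {c}")
    cols, oh, ow = _im2col(x, kh, kw, stride, padding)
    out = cols @ weights.reshape(f, -1).T + bias
    out = out.transpose(0, 3, 1, 2)  # (N, F, oh, ow)
    if activation == "sigmoid":
        return sigmoid(out)
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation is None:
        return out
    raise ValueError(f"unknown activation {activation!r}")


def maxpool_forward(x: np.ndarray, kernel: int, stride: int,
                    mode: str = "max") -> np.ndarray:
    """Window max (default) or mean over each kernel window at the stride."""
    if kernel > min(x.shape[2], x.shape[3]):
        raise ValueError(f"pool kernel {kernel} exceeds input {x.shape[2:]}")
    n, c, _, _ = x.shape
    cols, oh, ow = _im2col(x, kernel, kernel, stride, 0)
    cols = cols.reshape(n, oh, ow, c, kernel * kernel)
    pooled = cols.max(axis=-1) if mode == "max" else cols.mean(axis=-1)
    return pooled.transpose(0, 3, 1, 2)


# ---------------------------------------------------------------------------
# layers with parameters and backprop
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, spec: LayerSpec, in_channels: int, rng: np.random.Generator,
                 activation: str, init: str):
        k, f = spec.kernel, spec.n_filters
        fan_in = in_channels * k * k
        fan_out = f * k * k
        if init == "unit":  # the printed [0, 1] scheme; saturates sigmoids
            self.w = rng.uniform(0.0, 1.0, (f, in_channels, k, k))
            self.b = rng.uniform(0.0, 1.0, f)
        else:
            # Glorot-uniform with the sigmoid gain of 4 so layer-to-layer
            # signal variance is preserved through the squashing
            gain = 4.0 if activation == "sigmoid" else 1.0
            bound = gain * np.sqrt(6.0 / (fan_in + fan_out))
            self.w = rng.uniform(-bound, bound, (f, in_channels, k, k))
            self.b = np.zeros(f)
        self.stride, self.pad, self.activation = spec.stride, spec.padding, activation

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        f, c, kh, kw = self.w.shape
        self.cols, oh, ow = _im2col(x, kh, kw, self.stride, self.pad)
        z = self.cols @ self.w.reshape(f, -1).T + self.b
        z = z.transpose(0, 3, 1, 2)
        if self.activation == "sigmoid":
            self.out = sigmoid(z)
        else:
            self.z = z
            self.out = np.maximum(z, 0.0)
        return self.out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            dz = dout * self.out * (1.0 - self.out)
        else:
            dz = dout * (self.z > 0)
        f = self.w.shape[0]
        dz_flat = dz.transpose(0, 2, 3, 1)  # (N, oh, ow, F)
        self.dw = np.tensordot(dz_flat, self.cols, axes=([0, 1, 2], [0, 1, 2])
                               ).reshape(self.w.shape)
        self.db = dz_flat.sum(axis=(0, 1, 2))
        dcols = dz_flat @ self.w.reshape(f, -1)
        kh, kw = self.w.shape[2], self.w.shape[3]
        return _col2im(dcols, self.x_shape, kh, kw, self.stride, self.pad)


class _MaxPool:
    def __init__(self, spec: LayerSpec, mode: str = "max"):
        self.k, self.stride, self.mode = spec.kernel, spec.stride, mode

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        n, c, _, _ = x.shape
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, 0)
        cols = cols.reshape(n, oh, ow, c, self.k * self.k)
        if self.mode == "max":
            self.argmax = cols.argmax(axis=-1)
            out = cols.max(axis=-1)
        else:
            out = cols.mean(axis=-1)
        self.oh, self.ow = oh, ow
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, oh, ow = dout.shape
        d = dout.transpose(0, 2, 3, 1)  # (N, oh, ow, C)
        dcols = np.zeros((n, oh, ow, c, self.k * self.k))
        if self.mode == "max":
            np.put_along_axis(dcols, self.argmax[..., None], d[..., None], axis=-1)
        else:
            dcols += (d / (self.k * self.k))[..., None]
        dcols = dcols.reshape(n, oh, ow, c * self.k * self.k)
        return _col2im(dcols, self.x_shape, self.k, self.k, self.stride, 0)


class _Dense:
    def __init__(self, in_units: int, out_units: int, rng: np.random.Generator,
                 activation: str | None, init: str):
        if init == "unit":
            self.w = rng.uniform(0.0, 1.0, (in_units, out_units))
            self.b = rng.uniform(0.0, 1.0, out_units)
        else:
            gain = 4.0 if activation == "sigmoid" else 1.0
            bound = gain * np.sqrt(6.0 / (in_units + out_units))
            self.w = rng.uniform(-bound, bound, (in_units, out_units))
            self.b = np.zeros(out_units)
        self.activation = activation

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        z = x @ self.w + self.b
        if self.activation == "sigmoid":
            self.out = sigmoid(z)
        elif self.activation == "relu":
            self.z = z
            self.out = np.maximum(z, 0.0)
        else:
            self.out = z
        return self.out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            dz = dout * self.out * (1.0 - self.out)
        elif self.activation == "relu":
            dz = dout * (self.z > 0)
        else:
            dz = dout
        self.dw = self.x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.w.T


class Network:
    """The layer chain with its parameters; forward produces class probabilities."""

    def __init__(self, arch: tuple[LayerSpec, ...], class_count: int, seed: int = 0,
                 activation: str = "sigmoid", init: str = "fan_in",
                 pool_mode: str = "max"):
        if class_count < 2:
            raise ValueError("class_count must be >= 2")
        self.arch = tuple(arch)
        self.class_count = class_count
        self.seed = seed
        rng = np.random.default_rng(seed)
        if arch[0].kind != "input":
            raise ValueError("architecture must start with an input layer")
        self.input_size = arch[0].size
        self.input_channels = arch[0].channels
        size, channels = arch[0].size, arch[0].channels
        flat: int | None = None
        self.layers: list = []
        for li, spec in enumerate(arch[1:], start=1):
            if spec.kind == "conv":
                size_next = (size + 2 * spec.padding - spec.kernel) // spec.stride + 1
                if size_next < 1:
                    raise ValueError(f"layer {li} ({spec.kind}) collapses spatial size")
                self.layers.append(_Conv(spec, channels, rng, activation, init))
                channels, size = spec.n_filters, size_next
            elif spec.kind == "maxpool":
                size_next = (size - spec.kernel) // spec.stride + 1
                if size_next < 1:
                    raise ValueError(f"layer {li} ({spec.kind}) collapses spatial size")
                self.layers.append(_MaxPool(spec, pool_mode))
                size = size_next
            elif spec.kind == "fully_connected":
                if flat is None:
                    flat = channels * size * size
                self.layers.append(_Dense(flat, spec.out_units, rng, activation, init))
                flat = spec.out_units
            elif spec.kind == "output":
                if flat is None:
                    flat = channels * size * size
                self.layers.append(_Dense(flat, class_count, rng, None, init))
                flat = class_count
            else:
                raise ValueError(f"unknown layer kind {spec.kind!r}")
        self.class_names: list[str] | None = None

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, C, H, W) -> class probabilities (N, class_count).

        The preprocessing layer standardizes each sample to zero mean and
        unit variance before the convolutional chain.
        """
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True)
        out = (x - mu) / np.maximum(sd, 1e-6)
        flattened = False
        self._pre_flatten_shape: tuple | None = None
        for layer in self.layers:
            if isinstance(layer, _Dense) and not flattened:
                self._pre_flatten_shape = out.shape
                out = out.reshape(out.shape[0], -1)
                flattened = True
            out = layer.forward(out)
        return softmax(out)

    def backward(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        """Backpropagate the summed cross-entropy gradient (softmax fused)."""
        dout = probs - onehot
        for layer in reversed(self.layers):
            if not isinstance(layer, _Dense) and dout.ndim == 2:
                dout = dout.reshape(self._pre_flatten_shape)
            dout = layer.backward(dout)

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "w"):
                params[f"w{i}"] = layer.w
                params[f"b{i}"] = layer.b
        return params

    def gradients(self) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "dw"):
                grads[f"w{i}"] = layer.dw
                grads[f"b{i}"] = layer.db
        return grads

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "w"):
                layer.w = params[f"w{i}"]
                layer.b = params[f"b{i}"]

    def weight_sq_norm(self) -> float:
        return float(sum((layer.w ** 2).sum() for layer in self.layers
                         if hasattr(layer, "w")))


def build_network(arch: tuple[LayerSpec, ...], class_count: int, seed: int = 0,
                  **kwargs) -> Network:
    """Seeded network construction; same seed gives identical parameters."""
    return Network(arch, class_count, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# objective, update, training
# ---------------------------------------------------------------------------

def loss(probabilities: np.ndarray, labels: np.ndarray, network: Network | None = None,
         l2_coeff: float = 0.0) -> float:
    """Summed cross-entropy over samples and classes plus l2_coeff * ||W||^2.

    Probabilities at a true class are floored at 1e-12 before the log.
    """
    p = np.clip(probabilities, LOG_FLOOR, 1.0)
    ce = float(-(labels * np.log(p)).sum())
    if l2_coeff and network is not None:
        ce += l2_coeff * network.weight_sq_norm()
    return ce


def sgd_step(params: dict[str, np.ndarray], gradients: dict[str, np.ndarray],
             learning_rate: float, n: int) -> dict[str, np.ndarray]:
    """w(l+1) = w(l) - (eta / N) * accumulated gradient."""
    out: dict[str, np.ndarray] = {}
    for key, value in params.items():
        g = gradients[key]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {key!r}")
        out[key] = value - (learning_rate / n) * g
    return out


@dataclass
class TrainingConfig:
    """Optimization settings; the published initial learning rate is 1e-4."""

    learning_rate: float = 0.0001
    l2_coeff: float = 0.0
    epochs: int = 20
    batch_size: int = 32
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")


@dataclass
class TrainingState:
    """Per-epoch records of the optimization."""

    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    n_samples: int = 0
    residuals: np.ndarray | None = None  # t_n - y_n on the last batch


def _samples_to_arrays(samples, class_names: list[str], channels: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    index = {c: i for i, c in enumerate(class_names)}
    x = np.stack([np.asarray(s.patch, dtype=float) for s in samples])[:, None, :, :]
    if channels > 1:
        x = np.repeat(x, channels, axis=1)
    y = np.zeros((len(samples), len(class_names)))
    for i, s in enumerate(samples):
        y[i, index[s.label]] = 1.0
    return x, y


def train(dataset, config: TrainingConfig, arch: tuple[LayerSpec, ...] | None = None,
          network: Network | None = None) -> tuple[Network, TrainingState]:
    """Mini-batch SGD over the training split with per-epoch validation.

    ``dataset`` is a DatasetSplit; the class vocabulary is the sorted set of
    labels present in its training split.
    """
    if not dataset.train:
        raise ValueError("training split is empty")
    class_names = sorted({s.label for s in dataset.train})
    patch = np.asarray(dataset.train[0].patch)
    if network is None:
        if arch is None:
            arch = toy_arch(input_size=patch.shape[0], channels=1)
        network = build_network(arch, class_count=len(class_names), seed=config.seed)
    network.class_names = class_names
    x_train, y_train = _samples_to_arrays(dataset.train, class_names,
                                          network.input_channels)
    has_val = bool(dataset.validation)
    if has_val:
        x_val, y_val = _samples_to_arrays(dataset.validation, class_names,
                                          network.input_channels)
    rng = np.random.default_rng(config.seed)
    state = TrainingState(n_samples=len(dataset.train))
    n = len(dataset.train)
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay ** epoch
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs = network.forward(xb)
            total_loss += loss(probs, yb, network, config.l2_coeff)
            correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            network.backward(probs, yb)
            grads = network.gradients()
            if config.l2_coeff:
                for key in grads:
                    if key.startswith("w"):
                        grads[key] = grads[key] + 2.0 * config.l2_coeff * \
                            network.parameters()[key]
            network.set_parameters(sgd_step(network.parameters(), grads,
                                            lr, len(idx)))
            state.residuals = yb - probs
        state.epoch_loss.append(total_loss)
        state.epoch_accuracy.append(correct / n)
        if has_val:
            val_probs = _predict_in_batches(network, x_val)
            state.val_accuracy.append(
                float((val_probs.argmax(axis=1) == y_val.argmax(axis=1)).mean()))
    return network, state


def _predict_in_batches(network: Network, x: np.ndarray, batch: int = 256) -> np.ndarray:
    return np.concatenate([network.forward(x[i:i + batch])
                           for i in range(0, len(x), batch)])


def predict_patch(network: Network, patch: np.ndarray) -> np.ndarray:
    """Class probability vector for one 2D patch (probabilities sum to 1)."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (network.input_size, network.input_size):
        raise ValueError(
            f"patch shape {patch.shape} does not match network input "
            f"{network.input_size}x{network.input_size}")
    x = patch[None, None, :, :]
    if network.input_channels > 1:
        x = np.repeat(x, network.input_channels, axis=1)
    return network.forward(x)[0]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

def save_model(network: Network, path: str | Path) -> None:
    """Single-file container: layer specs + class names (JSON) + flat arrays."""
    meta = {
        "arch": [vars(s) for s in network.arch],
        "class_count": network.class_count,
        "seed": network.seed,
        "class_names": network.class_names,
    }
    arrays = {k: v for k, v in network.parameters().items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arch = tuple(LayerSpec(**d) for d in meta["arch"])
        net = Network(arch, meta["class_count"], seed=meta["seed"])
        net.set_parameters({k: data[k] for k in data.files if k != "__meta__"})
        net.class_names = meta["class_names"]
    return net
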