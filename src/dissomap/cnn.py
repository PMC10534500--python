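"""Particle-size regression from HPMC concentration maps with a small CNN.

The network reads a single-channel concentration map (31x31 for Raman,
48x48 for NIR) and regresses the HPMC sieve size label, defined as the pore
size of the smallest sieve the particles could pass through (45, 63, 100 or
150 µm).  Architecture: repeated blocks of convolution -> ReLU -> dropout ->
batch normalization -> 2x2 average pooling, then a fully-connected layer and
a scalar linear output trained with mean squared error.  Training uses Adam
with a staircase learning-rate schedule lr(e) = lr0 * drop^floor((e-1)/period).

Implemented directly on numpy (im2col convolutions, analytic backprop): the
tensors involved are tiny, and a from-scratch implementation keeps training
bit-reproducible for a fixed seed.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .unmix import ConcentrationMap

__all__ = [
    "CNNArchitecture",
    "CNNTrainConfig",
    "InvalidArchitectureError",
    "TrainingDivergedError",
    "ParticleSizeCNN",
    "TrainingHistory",
    "build_particle_cnn",
    "train_particle_cnn",
    "predict_size",
    "split_train_val",
    "learning_rate_at_epoch",
]

#: inference-time clip bounds for the predicted size, µm
SIZE_CLIP_UM = (22.5, 200.0)


class InvalidArchitectureError(ValueError):
    """Pooling/convolution would reduce a spatial dimension below 1."""


class TrainingDivergedError(RuntimeError):
    """Non-finite loss encountered; carries the epoch index."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"non-finite training loss {loss} at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class CNNArchitecture:
    """Shape hyperparameters of the block structure (see module docstring)."""

    n_blocks: int = 2
    n_filters: tuple[int, ...] = (8, 16)
    kernel_size: tuple[int, ...] = (3, 5)
    dropout_rate: float = 0.2
    pool_size: int | tuple[int, ...] = (2, 9)
    dense_units: int = 16

    def __post_init__(self) -> None:
        if len(self.n_filters) != self.n_blocks or len(self.kernel_size) != self.n_blocks:
            raise InvalidArchitectureError("n_filters/kernel_size must have n_blocks entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidArchitectureError("dropout_rate must be in [0, 1)")
        pools = self.pool_sizes
        if len(pools) != self.n_blocks or any(p < 1 for p in pools):
            raise InvalidArchitectureError("pool sizes must be >= 1, one per block")

    @property
    def pool_sizes(self) -> tuple[int, ...]:
        if isinstance(self.pool_size, int):
            return (self.pool_size,) * self.n_blocks
        return tuple(self.pool_size)


@dataclass(frozen=True)
class CNNTrainConfig:
    """Training schedule (Adam, staircase learning-rate decay)."""

    initial_lr: float = 0.001
    lr_drop_period: int = 10
    lr_drop_factor: float = 0.9
    max_epochs: int = 100
    validation_every: int = 5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.lr_drop_period, self.lr_drop_factor,
               self.max_epochs, self.validation_every, self.batch_size) <= 0:
            raise ValueError("all CNNTrainConfig values must be positive")


def learning_rate_at_epoch(epoch: int, cfg: CNNTrainConfig) -> float:
    """Staircase schedule lr0 * factor^floor((epoch-1)/period); epoch is 1-based."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return cfg.initial_lr * cfg.lr_drop_factor ** ((epoch - 1) // cfg.lr_drop_period)


# ---------------------------------------------------------------------------
# layers: each has forward(x, training, rng) and backward(grad) -> grad_input;
# trainable layers expose .params / .grads dicts of matching keys.


class _Conv2D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.params = {
            "w": rng.normal(0.0, scale, size=(c_in * k * k, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x, training, rng):
        n, h, w, _ = x.shape
        k = self.k
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (n, ho, wo, c, k, k)
        ho, wo = h - k + 1, w - k + 1
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * self.c_in)
        # weight layout matches (k, k, c_in) flattened
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.params["w"] + self.params["b"]
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, grad):
        n, ho, wo, _ = grad.shape
        g = grad.reshape(-1, self.c_out)
        self.grads["w"][...] = self._cols.T @ g
        self.grads["b"][...] = g.sum(axis=0)
        k = self.k
        gcols = (g @ self.params["w"].T).reshape(n, ho, wo, k, k, self.c_in)
        dx = np.zeros(self._xshape)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + ho, j : j + wo, :] += gcols[:, :, :, i, j, :]
        return dx


class _ReLU:
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _BatchNorm:
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes])) if training else 0
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.grads["gamma"][...] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = grad.sum(axis=axes)
        g = grad * self.params["gamma"]
        if not self._training:
            return g / self._std
        m = self._m
        return (
            g - g.mean(axis=axes) - self._xhat * (g * self._xhat).mean(axis=axes)
        ) / self._std


class _AvgPool2D:
    def __init__(self, p: int):
        self.p = p

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        p = self.p
        ho, wo = h // p, w // p
        self._in_shape = x.shape
        xc = x[:, : ho * p, : wo * p, :]
        return xc.reshape(n, ho, p, wo, p, c).mean(axis=(2, 4))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        p = self.p
        ho, wo = h // p, w // p
        dx = np.zeros(self._in_shape)
        up = np.repeat(np.repeat(grad, p, axis=1), p, axis=2) / (p * p)
        dx[:, : ho * p, : wo * p, :] = up
        return dx


class _Flatten:
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.params = {"w": rng.normal(0.0, scale, size=(n_in, n_out)), "b": np.zeros(n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad):
        self.grads["w"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["w"].T


class _Adam:
    def __init__(self, layers, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = []
        for layer in layers:
            if hasattr(layer, "params"):
                for key in layer.params:
                    self.slots.append(
                        (layer, key, np.zeros_like(layer.params[key]), np.zeros_like(layer.params[key]))
                    )
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, key, m, v in self.slots:
            g = layer.grads[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[key] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    """Per-epoch training loss, periodic validation loss, learning rates."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: dict[int, float] = field(default_factory=dict)
    learning_rates: list[float] = field(default_factory=list)
    termination: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "lr": self.learning_rates,
                "val_loss": [self.val_loss.get(e, np.nan) for e in range(1, len(self.train_loss) + 1)],
            }
        )


class ParticleSizeCNN:
    """The CNN model plus its input/target scaling.

    Maps enter in w/w % and are divided by 100; size labels are z-scored on
    the training set.  Predictions are de-standardized and clipped to
    [22.5, 200] µm so downstream models see sizes in the trained domain.
    """

    def __init__(self, input_shape: tuple[int, int], arch: CNNArchitecture, seed: int = 0):
        h, w = input_shape
        if h < 8 or w < 8:
            raise InvalidArchitectureError("input maps must be at least 8x8")
        self.input_shape = (int(h), int(w))
        self.arch = arch
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in, hh, ww = 1, h, w
        for blk in range(arch.n_blocks):
            k, c_out = arch.kernel_size[blk], arch.n_filters[blk]
            pool = arch.pool_sizes[blk]
            hh, ww = hh - k + 1, ww - k + 1
            if hh < 1 or ww < 1:
                raise InvalidArchitectureError(f"conv block {blk} output {hh}x{ww}")
            layers += [
                _Conv2D(c_in, c_out, k, rng),
                _ReLU(),
                _Dropout(arch.dropout_rate),
                _BatchNorm(c_out),
                _AvgPool2D(pool),
            ]
            hh, ww = hh // pool, ww // pool
            if hh < 1 or ww < 1:
                raise InvalidArchitectureError(f"pool in block {blk} reduced output to {hh}x{ww}")
            c_in = c_out
        layers += [
            _Flatten(),
            _Dense(hh * ww * c_in, arch.dense_units, rng),
            _ReLU(),
            _Dense(arch.dense_units, 1, rng),
        ]
        self.layers = layers
        self.label_mean = 0.0
        self.label_std = 1.0
        self.fitted = False

    @property
    def n_parameters(self) -> int:
        return sum(
            v.size for l in self.layers if hasattr(l, "params") for v in l.params.values()
        )

    def _forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_scaled(self, maps: np.ndarray) -> np.ndarray:
        """Raw network output (z-scored label units) in eval mode."""
        x = np.asarray(maps, dtype=float) / 100.0
        if x.ndim == 3:
            x = x[..., None]
        return self._forward(x, training=False, rng=None)[:, 0]

    def predict(self, maps: np.ndarray) -> np.ndarray:
        """Predicted sieve size labels in µm, clipped to the trained domain."""
        z = self.predict_scaled(maps)
        return np.clip(z * self.label_std + self.label_mean, *SIZE_CLIP_UM)


def build_particle_cnn(
    input_shape: tuple[int, int], arch: CNNArchitecture | None = None, seed: int = 0
) -> ParticleSizeCNN:
    """Construct an untrained particle-size CNN for maps of ``input_shape``."""
    return ParticleSizeCNN(input_shape, arch or CNNArchitecture(), seed)


def _as_map_array(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps.astype(float)
    arrs = [m.values if isinstance(m, ConcentrationMap) else np.asarray(m, float) for m in maps]
    return np.stack(arrs)


def train_particle_cnn(
    model: ParticleSizeCNN,
    train_maps,
    train_labels,
    val_maps=None,
    val_labels=None,
    cfg: CNNTrainConfig | None = None,
) -> TrainingHistory:
    """Train in place with Adam + staircase LR; returns the history.

    Maps may be ConcentrationMap objects or (N, H, W) arrays in w/w %;
    labels are sieve sizes in µm.  Raises TrainingDivergedError on a
    non-finite loss.
    """
    cfg = cfg or CNNTrainConfig()
    x = _as_map_array(train_maps) / 100.0
    y = np.asarray(train_labels, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("number of maps and labels differ")
    if x.shape[1:] != model.input_shape:
        raise ValueError(f"map shape {x.shape[1:]} != model input {model.input_shape}")
    model.label_mean = float(y.mean())
    model.label_std = float(y.std()) or 1.0
    yz = (y - model.label_mean) / model.label_std
    x = x[..., None]

    has_val = val_maps is not None and val_labels is not None
    if has_val:
        xv = _as_map_array(val_maps) / 100.0
        yv = (np.asarray(val_labels, dtype=float) - model.label_mean) / model.label_std

    rng = np.random.default_rng(cfg.seed)
    optimizer = _Adam([l for l in model.layers if hasattr(l, "params")])
    history = TrainingHistory()
    n = x.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        lr = learning_rate_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], yz[idx]
            pred = model._forward(xb, training=True, rng=rng)[:, 0]
            residual = pred - yb
            loss = float(np.mean(residual**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch, loss)
            epoch_loss += loss * idx.size
            model._backward((2.0 * residual / idx.size)[:, None])
            optimizer.step(lr)
        history.train_loss.append(epoch_loss / n)
        history.learning_rates.append(lr)
        if has_val and epoch % cfg.validation_every == 0:
            pv = model.predict_scaled(_as_map_array(val_maps))
            history.val_loss[epoch] = float(np.mean((pv - yv) ** 2))
    history.termination = f"max_epochs ({cfg.max_epochs}) reached"
    model.fitted = True
    return history


def predict_size(model: ParticleSizeCNN, cmap) -> float:
    """Predicted HPMC sieve size (µm) for one concentration map."""
    values = cmap.values if isinstance(cmap, ConcentrationMap) else np.asarray(cmap, float)
    if values.shape != model.input_shape:
        raise ValueError(f"map shape {values.shape} != model input {model.input_shape}")
    return float(model.predict(values[None])[0])


def split_train_val(records, n_val: int, seed: int = 0, strata_key=None):
    """Deterministic stratified split of a record list into (train, val).

    Stratification is by ``strata_key`` (default: the record's design name,
    which encodes the concentration level x size fraction combination); one
    record per stratum is offered to the validation pool round-robin until
    ``n_val`` is reached, so validation covers the strata as evenly as
    divisibility allows.
    """
    records = list(records)
    if n_val >= len(records):
        raise ValueError(f"n_val={n_val} must be smaller than the dataset ({len(records)})")
    if strata_key is None:
        strata_key = lambda r: getattr(getattr(r, "design", r), "name", str(r))  # noqa: E731
    rng = np.random.default_rng(seed)
    strata: dict = {}
    for i, rec in enumerate(records):
        strata.setdefault(strata_key(rec), []).append(i)
    if sum(len(m) - 1 for m in strata.values()) < n_val:
        # too few replicates to stratify; plain shuffled split
        perm = rng.permutation(len(records))
        val_idx = perm[:n_val].tolist()
        train = [records[i] for i in perm[n_val:]]
        return train, [records[i] for i in val_idx]
    for members in strata.values():
        rng.shuffle(members)
    order = sorted(strata)
    rng.shuffle(order)
    val_idx: list[int] = []
    round_ = 0
    while len(val_idx) < n_val:
        progressed = False
        for key in order:
            members = strata[key]
            if round_ < len(members) - 1:  # never empty a stratum's train side
                val_idx.append(members[round_])
                progressed = True
                if len(val_idx) == n_val:
                    break
        if not progressed:
            raise ValueError("cannot reach n_val without emptying a stratum")
        round_ += 1
    val_set = set(val_idx)
    train = [records[i] for i in range(len(records)) if i not in val_set]
    val = [records[i] for i in val_idx]
    return train, val


# ---------------------------------------------------------------------------
# serialization: one portable .npz with the architecture config embedded


def save_cnn(model: ParticleSizeCNN, path) -> None:
    meta = {
        "input_shape": model.input_shape,
        "arch": asdict(model.arch),
        "seed": model.seed,
        "label_mean": model.label_mean,
        "label_std": model.label_std,
        "fitted": model.fitted,
    }
    arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, layer in enumerate(model.layers):
        if hasattr(layer, "params"):
            for key, val in layer.params.items():
                arrays[f"layer{i}_{key}"] = val
        if isinstance(layer, _BatchNorm):
            arrays[f"layer{i}_running_mean"] = layer.running_mean
            arrays[f"layer{i}_running_var"] = layer.running_var
    np.savez(path, **arrays)


def load_cnn(path) -> ParticleSizeCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        arch = CNNArchitecture(
            n_blocks=meta["arch"]["n_blocks"],
            n_filters=tuple(meta["arch"]["n_filters"]),
            kernel_size=tuple(meta["arch"]["kernel_size"]),
            dropout_rate=meta["arch"]["dropout_rate"],
            pool_size=meta["arch"]["pool_size"],
            dense_units=meta["arch"]["dense_units"],
        )
        model = ParticleSizeCNN(tuple(meta["input_shape"]), arch, meta["seed"])
        for i, layer in enumerate(model.layers):
            if hasattr(layer, "params"):
                for key in layer.params:
                    layer.params[key][...] = data[f"layer{i}_{key}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean[...] = data[f"layer{i}_running_mean"]
                layer.running_var[...] = data[f"layer{i}_running_var"]
        model.label_mean = meta["label_mean"]
        model.label_std = meta["label_std"]
        model.fitted = meta["fitted"]
    return model
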