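"""A compact 3-D convolutional network for volumetric two-class decisions.

The architecture maps one entropy volume to a two-class softmax:

    avgpool(2^3) -> conv(32, 3^3) -> maxpool(2^3) -> batchnorm
                 -> conv(64, 3^3) -> maxpool(2^3) -> batchnorm
                 -> conv(128, 2^3) -> flatten
                 -> fc 500 -> fc 500 -> fc 500 -> fc 2 (softmax)

with ReLU after every trainable layer except the softmax output.
Convolutions are unpadded ("valid") and pooling uses floor division, which
keeps the first fully connected layer as small as possible.  Training
minimizes categorical cross-entropy with the Adam optimizer and stops
early when the monitored loss has not improved for a set number of epochs,
restoring the best weights.

Everything is implemented directly on numpy arrays: convolutions are
evaluated as tensor contractions over sliding windows, and gradients are
derived analytically per layer (verified by finite differences in the test
suite).  A reduced "desk-scale" specification with the same layer sequence
but far fewer parameters is provided for small toy volumes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ArchitectureError",
    "ModelSpec",
    "TrainHyper",
    "TrainedSeedModel",
    "build_model",
    "desk_scale_spec",
    "CNNVolumeClassifier",
]


class ArchitectureError(ValueError):
    """A layer stack does not fit the given input extents."""


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class ModelSpec:
    """Layer hyperparameters of the volumetric classifier."""

    input_extents: tuple[int, int, int]
    avgpool_size: int = 2
    conv_filters: tuple[int, ...] = (32, 64, 128)
    conv_kernels: tuple[int, ...] = (3, 3, 2)
    maxpool_sizes: tuple[int, ...] = (2, 2)
    batchnorm: bool = True
    pool_then_norm: bool = True
    fc_widths: tuple[int, ...] = (500, 500, 500, 2)

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels lengths differ")
        if len(self.maxpool_sizes) != len(self.conv_filters) - 1:
            raise ValueError("need one maxpool size per conv layer except the last")
        if self.fc_widths[-1] != 2:
            raise ValueError("final layer width must be 2 (two-class softmax)")
        self.layer_summary()  # validates extents

    def layer_summary(self) -> list[dict]:
        """Layer sequence with output shapes and parameter shapes.

        Raises :class:`ArchitectureError` naming the first layer whose
        output would collapse to zero extent.
        """
        summary: list[dict] = []
        shape = tuple(self.input_extents)
        channels = 1

        def shrink(name, new_shape):
            if any(s < 1 for s in new_shape):
                raise ArchitectureError(
                    f"layer {name!r} reduces extents to {new_shape}; "
                    f"input {self.input_extents} is too small for this stack"
                )
            return new_shape

        if self.avgpool_size > 1:
            shape = shrink("avgpool", tuple(s // self.avgpool_size for s in shape))
            summary.append({"layer": "avgpool", "size": self.avgpool_size,
                            "output": (channels, *shape), "params": {}})
        for i, (f, k) in enumerate(zip(self.conv_filters, self.conv_kernels), start=1):
            shape = shrink(f"conv{i}", tuple(s - k + 1 for s in shape))
            summary.append({
                "layer": f"conv{i}", "filters": f, "kernel": (k, k, k),
                "output": (f, *shape),
                "params": {"weight": (f, channels, k, k, k), "bias": (f,)},
            })
            channels = f
            summary.append({"layer": f"relu{i}", "output": (channels, *shape),
                            "params": {}})
            if i <= len(self.maxpool_sizes):
                p = self.maxpool_sizes[i - 1]
                blocks = [("maxpool", p), ("batchnorm", None)]
                if not self.pool_then_norm:
                    blocks.reverse()
                for kind, size in blocks:
                    if kind == "maxpool" and p > 1:
                        shape = shrink(f"maxpool{i}", tuple(s // p for s in shape))
                        summary.append({"layer": f"maxpool{i}", "size": p,
                                        "output": (channels, *shape), "params": {}})
                    elif kind == "batchnorm" and self.batchnorm:
                        summary.append({
                            "layer": f"batchnorm{i}", "output": (channels, *shape),
                            "params": {"gamma": (channels,), "beta": (channels,)},
                        })
        n_flat = channels * int(np.prod(shape))
        summary.append({"layer": "flatten", "output": (n_flat,), "params": {}})
        width_in = n_flat
        for j, width in enumerate(self.fc_widths, start=1):
            summary.append({
                "layer": f"fc{j}", "output": (width,),
                "params": {"weight": (width_in, width), "bias": (width,)},
            })
            if j < len(self.fc_widths):
                summary.append({"layer": f"relu_fc{j}", "output": (width,),
                                "params": {}})
            width_in = width
        summary.append({"layer": "softmax", "output": (2,), "params": {}})
        return summary


def build_model(input_extents: tuple[int, int, int], **overrides) -> ModelSpec:
    """Validated specification for the given input extents.

    Overrides (e.g. smaller filter counts for desk-scale tests) are applied
    on top of the default full-size architecture and recorded in the spec
    itself, which travels with every trained model.
    """
    return ModelSpec(input_extents=tuple(int(e) for e in input_extents), **overrides)


def desk_scale_spec(input_extents: tuple[int, int, int]) -> ModelSpec:
    """Reduced profile for small toy volumes: same layer sequence, ~10^3
    fewer parameters (filters 4/8/8, fc width 32, second maxpool dropped)."""
    return build_model(
        input_extents,
        conv_filters=(4, 8, 8),
        conv_kernels=(3, 3, 2),
        maxpool_sizes=(2, 1),
        fc_widths=(32, 32, 32, 2),
    )


@dataclass(frozen=True)
class TrainHyper:
    """Optimization settings: Adam, categorical cross-entropy, early stop."""

    max_epochs: int = 400
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size, self.early_stop_patience) < 1:
            raise ValueError("epochs, batch size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainedSeedModel:
    """A fitted per-seed-ROI classifier with its training record."""

    spec: ModelSpec
    classifier: "CNNVolumeClassifier"
    seed_roi: int
    history: dict
    best_epoch: int


# ---------------------------------------------------------------------------
# layers (numpy forward/backward)


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, delta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


class _Conv3d(_Layer):
    def __init__(self, in_channels, filters, kernel, rng):
        super().__init__()
        k = kernel
        fan_in = in_channels * k**3
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(filters, in_channels, k, k, k)),
            "b": np.zeros(filters),
        }
        self.kernel = k

    def forward(self, x, train):
        k = self.kernel
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        self._win = win if train else None
        out = np.tensordot(win, self.params["w"], axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        out = out + self.params["b"]
        self._in_shape = x.shape
        return np.moveaxis(out, -1, 1)

    def backward(self, delta):
        k = self.kernel
        d = np.moveaxis(delta, 1, -1)  # (B, D', H', W', F)
        self.grads["w"] = np.tensordot(d, self._win, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
        self.grads["b"] = d.sum(axis=(0, 1, 2, 3))
        # full correlation of delta with the flipped kernels gives dX
        pad = [(0, 0), (0, 0)] + [(k - 1, k - 1)] * 3
        dpad = np.pad(delta, pad)
        win = sliding_window_view(dpad, (k, k, k), axis=(2, 3, 4))
        wflip = self.params["w"][:, :, ::-1, ::-1, ::-1]
        dx = np.tensordot(win, wflip, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
        self._win = None
        return np.moveaxis(dx, -1, 1)


def _pool_blocks(x: np.ndarray, p: int) -> tuple[np.ndarray, tuple]:
    b, c, d, h, w = x.shape
    d2, h2, w2 = d // p, h // p, w // p
    cropped = x[:, :, : d2 * p, : h2 * p, : w2 * p]
    blocks = cropped.reshape(b, c, d2, p, h2, p, w2, p)
    blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d2, h2, w2, p**3)
    return blocks, (b, c, d, h, w, d2, h2, w2)


def _unpool(delta_blocks: np.ndarray, shape_info: tuple, p: int) -> np.ndarray:
    b, c, d, h, w, d2, h2, w2 = shape_info
    g = delta_blocks.reshape(b, c, d2, h2, w2, p, p, p)
    g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d2 * p, h2 * p, w2 * p)
    out = np.zeros((b, c, d, h, w))
    out[:, :, : d2 * p, : h2 * p, : w2 * p] = g
    return out


class _AvgPool3d(_Layer):
    def __init__(self, size):
        super().__init__()
        self.p = size

    def forward(self, x, train):
        blocks, self._info = _pool_blocks(x, self.p)
        return blocks.mean(axis=-1)

    def backward(self, delta):
        p3 = self.p**3
        blocks = np.repeat(delta[..., None] / p3, p3, axis=-1)
        return _unpool(blocks, self._info, self.p)


class _MaxPool3d(_Layer):
    def __init__(self, size):
        super().__init__()
        self.p = size

    def forward(self, x, train):
        blocks, self._info = _pool_blocks(x, self.p)
        self._argmax = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, delta):
        blocks = np.zeros(self._argmax.shape + (self.p**3,))
        np.put_along_axis(blocks, self._argmax[..., None], delta[..., None], axis=-1)
        return _unpool(blocks, self._info, self.p)


class _BatchNorm(_Layer):
    """Per-channel normalization over batch and spatial axes."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._inv_std.reshape(shape)
        return (self.params["gamma"].reshape(shape) * self._xhat
                + self.params["beta"].reshape(shape))

    def backward(self, delta):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        n = delta.shape[0] * delta.shape[2] * delta.shape[3] * delta.shape[4]
        self.grads["gamma"] = (delta * self._xhat).sum(axis=axes)
        self.grads["beta"] = delta.sum(axis=axes)
        coeff = (self.params["gamma"] * self._inv_std / n).reshape(shape)
        dx = coeff * (
            n * delta
            - self.grads["beta"].reshape(shape)
            - self._xhat * self.grads["gamma"].reshape(shape)
        )
        self._xhat = None
        return dx

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()
        super().load_state({k: v for k, v in state.items()
                            if k in ("gamma", "beta")})


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, delta):
        return delta * self._mask


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, delta):
        return delta.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, delta):
        self.grads["w"] = self._x.T @ delta
        self.grads["b"] = delta.sum(axis=0)
        dx = delta @ self.params["w"].T
        self._x = None
        return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    """Layer stack built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers: list[tuple[str, _Layer]] = []
        channels = 1
        shape = tuple(spec.input_extents)
        if spec.avgpool_size > 1:
            self.layers.append(("avgpool", _AvgPool3d(spec.avgpool_size)))
            shape = tuple(s // spec.avgpool_size for s in shape)
        for i, (f, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels), start=1):
            self.layers.append((f"conv{i}", _Conv3d(channels, f, k, rng)))
            shape = tuple(s - k + 1 for s in shape)
            channels = f
            self.layers.append((f"relu{i}", _ReLU()))
            if i <= len(spec.maxpool_sizes):
                p = spec.maxpool_sizes[i - 1]
                blocks = [("maxpool", p), ("batchnorm", None)]
                if not spec.pool_then_norm:
                    blocks.reverse()
                for kind, size in blocks:
                    if kind == "maxpool" and p > 1:
                        self.layers.append((f"maxpool{i}", _MaxPool3d(p)))
                        shape = tuple(s // p for s in shape)
                    elif kind == "batchnorm" and spec.batchnorm:
                        self.layers.append((f"batchnorm{i}", _BatchNorm(channels)))
        self.layers.append(("flatten", _Flatten()))
        width_in = channels * int(np.prod(shape))
        for j, width in enumerate(spec.fc_widths, start=1):
            self.layers.append((f"fc{j}", _Dense(width_in, width, rng)))
            if j < len(spec.fc_widths):
                self.layers.append((f"relu_fc{j}", _ReLU()))
            width_in = width

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim == 4:  # (batch, D, H, W) -> single-channel
            x = x[:, None]
        for _, layer in self.layers:
            x = layer.forward(x, train)
        return _softmax(x)

    def loss_and_grad(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        probs = self.forward(x, train=True)
        n = x.shape[0]
        loss = -np.sum(y_onehot * np.log(probs + 1e-12)) / n
        delta = (probs - y_onehot) / n
        for _, layer in reversed(self.layers):
            delta = layer.backward(delta)
        return float(loss)

    def evaluate_loss(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        probs = self.forward(x, train=False)
        return float(-np.sum(y_onehot * np.log(probs + 1e-12)) / x.shape[0])

    def state(self) -> dict:
        return {name: layer.state() for name, layer in self.layers}

    def load_state(self, state: dict) -> None:
        for name, layer in self.layers:
            if name in state:
                layer.load_state(state[name])

    def trainable(self):
        for name, layer in self.layers:
            for key in layer.params:
                yield name, key, layer


class _Adam:
    def __init__(self, net: _Network, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {(n, k): np.zeros_like(layer.params[k])
                  for n, k, layer in net.trainable()}
        self.v = {(n, k): np.zeros_like(layer.params[k])
                  for n, k, layer in net.trainable()}

    def step(self):
        self.t += 1
        for name, key, layer in self.net.trainable():
            g = layer.grads[key]
            slot = (name, key)
            self.m[slot] = self.beta1 * self.m[slot] + (1 - self.beta1) * g
            self.v[slot] = self.beta2 * self.v[slot] + (1 - self.beta2) * g * g
            mhat = self.m[slot] / (1 - self.beta1**self.t)
            vhat = self.v[slot] / (1 - self.beta2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# estimator


class CNNVolumeClassifier(ClassifierMixin, BaseEstimator):
    """Two-class volumetric CNN with scikit-learn fit/predict semantics.

    Parameters mirror :class:`TrainHyper`; ``spec`` defaults to the
    full-size architecture built for the training volumes' extents.  A
    validation set may be passed to ``fit`` for early-stopping; without
    one the training loss is monitored instead.  Training is deterministic
    given ``random_state``.
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        max_epochs: int = 400,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        early_stop_patience: int = 60,
        random_state: int = 0,
    ):
        self.spec = spec
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    # -- helpers

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            arr = X
        else:
            arr = np.stack([getattr(v, "values", v) for v in X])
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"expected (n, D, H, W) volumes, got shape {arr.shape}")
        return arr

    def _onehot(self, y: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.classes_, y)
        out = np.zeros((y.size, 2))
        out[np.arange(y.size), idx] = 1.0
        return out

    # -- estimator API

    def fit(self, X, y, validation_data: tuple | None = None):
        TrainHyper(
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stop_patience=self.early_stop_patience,
            seed=self.random_state,
        )  # validates
        X = self._as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"training set must contain both classes, got {self.classes_}"
            )
        spec = self.spec or build_model(X.shape[1:])
        if tuple(spec.input_extents) != X.shape[1:]:
            raise ValueError(
                f"volume extents {X.shape[1:]} do not match spec "
                f"{spec.input_extents}"
            )
        rng = np.random.default_rng(self.random_state)
        net = _Network(spec, rng)
        opt = _Adam(net, self.learning_rate)
        y_onehot = self._onehot(y)
        if validation_data is not None:
            X_val = self._as_array(validation_data[0])
            y_val = self._onehot(np.asarray(validation_data[1]))
        n = X.shape[0]
        history: dict[str, list[float]] = {"train_loss": [], "monitor_loss": []}
        best_loss = np.inf
        best_epoch = 0
        best_state = net.state()
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                loss = net.loss_and_grad(X[batch], y_onehot[batch])
                opt.step()
                epoch_loss += loss * batch.size
            epoch_loss /= n
            if validation_data is not None:
                monitor = net.evaluate_loss(X_val, y_val)
            else:
                monitor = epoch_loss
            history["train_loss"].append(epoch_loss)
            history["monitor_loss"].append(monitor)
            if monitor < best_loss:
                best_loss = monitor
                best_epoch = epoch
                best_state = net.state()
            if epoch - best_epoch >= self.early_stop_patience:
                break
        net.load_state(best_state)
        self.net_ = net
        self.spec_ = spec
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(history["train_loss"])
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        X = self._as_array(X)
        if tuple(self.spec_.input_extents) != X.shape[1:]:
            raise ValueError(
                f"volume extents {X.shape[1:]} do not match spec "
                f"{self.spec_.input_extents}"
            )
        chunks = [
            self.net_.forward(X[i : i + 64], train=False)
            for i in range(0, X.shape[0], 64)
        ]
        return np.concatenate(chunks)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def save(self, path) -> None:
        """Checkpoint the fitted network: an ``.npz`` of all layer arrays
        plus a JSON sidecar with the spec, hyperparameters and training
        record, and the loss history as TSV."""
        import dataclasses
        import json
        from pathlib import Path

        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        path = Path(path)
        arrays = {
            f"{name}/{key}": value
            for name, state in self.net_.state().items()
            for key, value in state.items()
        }
        arrays["classes"] = self.classes_
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "spec": dataclasses.asdict(self.spec_),
            "hyper": {
                "max_epochs": self.max_epochs,
                "batch_size": self.batch_size,
                "learning_rate": self.learning_rate,
                "early_stop_patience": self.early_stop_patience,
                "seed": self.random_state,
            },
            "best_epoch": self.best_epoch_,
            "n_epochs": self.n_epochs_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        import pandas as pd

        pd.DataFrame(self.history_).to_csv(
            path.with_suffix(".history.tsv"), sep="\t", index=False
        )

    @classmethod
    def load(cls, path) -> "CNNVolumeClassifier":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec_dict = sidecar["spec"]
        for key in ("input_extents", "conv_filters", "conv_kernels",
                    "maxpool_sizes", "fc_widths"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = ModelSpec(**spec_dict)
        hyper = sidecar["hyper"]
        clf = cls(
            spec=spec,
            max_epochs=hyper["max_epochs"],
            batch_size=hyper["batch_size"],
            learning_rate=hyper["learning_rate"],
            early_stop_patience=hyper["early_stop_patience"],
            random_state=hyper["seed"],
        )
        data = np.load(path.with_suffix(".npz"))
        net = _Network(spec, np.random.default_rng(hyper["seed"]))
        state: dict[str, dict] = {}
        for full_key in data.files:
            if full_key == "classes":
                continue
            name, key = full_key.split("/", 1)
            state.setdefault(name, {})[key] = data[full_key]
        net.load_state(state)
        clf.net_ = net
        clf.spec_ = spec
        clf.classes_ = data["classes"]
        clf.best_epoch_ = sidecar["best_epoch"]
        clf.n_epochs_ = sidecar["n_epochs"]
        clf.history_ = {}
        return clf

    def clone_unfitted(self) -> "CNNVolumeClassifier":
        return copy.deepcopy(
            CNNVolumeClassifier(
                spec=self.spec,
                max_epochs=self.max_epochs,
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                early_stop_patience=self.early_stop_patience,
                random_state=self.random_state,
            )
        )
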