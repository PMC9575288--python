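"""Neural-network building blocks on top of the autograd engine.

Layers follow the familiar Module convention: parameters are registered
attributes, ``train()`` / ``eval()`` toggle batch-statistics and dropout
behaviour, and ``state_dict`` / ``load_state_dict`` snapshot parameters and
buffers as plain NumPy arrays (used for best-validation checkpointing).
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, conv1d, maxpool1d

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...], dtype=DEFAULT_DTYPE) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / submodule discovery ------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state("", state)
        return state

    def _collect_state(self, prefix: str, state: dict) -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                state[key] = value.data.copy()
            elif isinstance(value, Module):
                value._collect_state(key + ".", state)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", state)
                    elif isinstance(item, Parameter):
                        state[f"{key}.{i}"] = item.data.copy()
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                state[key] = value.copy()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self._load_state("", state)

    def _load_state(self, prefix: str, state: dict) -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = state[key].copy()
            elif isinstance(value, Module):
                value._load_state(key + ".", state)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._load_state(f"{key}.{i}.", state)
                    elif isinstance(item, Parameter):
                        item.data = state[f"{key}.{i}"].copy()
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                value[...] = state[key]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.weight = Parameter(
            glorot_uniform(rng, in_features, out_features,
                           (in_features, out_features), dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Valid cross-correlation (padding 0, stride 1 by default)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, dtype=DEFAULT_DTYPE):
        super().__init__()
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.weight = Parameter(
            glorot_uniform(rng, fan_in, fan_out,
                           (out_channels, in_channels, kernel_size), dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride)


class MaxPool1d(Module):
    def __init__(self, window: int = 3, stride: int | None = None):
        super().__init__()
        self.window = window
        self.stride = window if stride is None else stride

    def forward(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.window, self.stride)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class BatchNorm1d(Module):
    """Batch standardization over the first axis of a (batch, features) input.

    Training mode standardizes with the batch statistics and updates running
    estimates; evaluation mode uses the running estimates, so a single sample
    gets the same prediction alone as inside any batch.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            if x.shape[0] < 2:
                raise ValueError("batch standardization needs batch size >= 2 in train mode")
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(self.running_var.dtype)
            xn = centered * (var + self.eps) ** -0.5
        else:
            xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Randomness comes from the
    generator handed to the layer (set once per training run for determinism)."""

    def __init__(self, p: float = 0.1):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in train mode without an rng; "
                               "call set_dropout_rng() on the network first")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.dtype))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def set_dropout_rng(module: Module, rng: np.random.Generator) -> None:
    for m in module.modules():
        if isinstance(m, Dropout):
            m.rng = rng


class Adam:
    """Adaptive moment estimation."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            # in-place moment updates keep the step memory-bandwidth friendly
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            denom = np.sqrt(v / b2t)
            denom += self.eps
            update = m / denom
            update *= self.lr / b1t
            p.data -= update
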