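"""Neural-network building blocks over the autodiff tape.

Layers follow the familiar torch-like contract (``Module`` with
``parameters()``, ``train()``/``eval()`` modes, batch-norm running
statistics) but are plain numpy underneath.  Initialization is explicit:
every layer draws its weights from a caller-supplied
``numpy.random.Generator`` so whole models are bit-reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "Conv2d", "BatchNorm1d", "ReLU", "Sequential", "Adam"]


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict of plain arrays, for checkpointing ------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    value.data = np.array(state[key], dtype=np.float64)
                elif isinstance(value, np.ndarray):
                    setattr(mod, name, np.array(state[key]))
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")


class Linear(Module):
    """Affine map x @ W + b with Kaiming-uniform initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = float(np.sqrt(6.0 / in_features))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Stride-1 2-D convolution (cross-correlation) with 'same' or no padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = Parameter(
            rng.uniform(-bound, bound,
                        size=(out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalization over features; batch statistics while training,
    exponential running averages in evaluation mode."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered / ((var + self.eps) ** 0.5)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            # unbiased estimate for the running buffer, as is conventional
            n = x.shape[0]
            unbias = n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel() * unbias
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with per-group learning rates (encoder / filters / proxies).

    A group may set ``"algo": "sgd"`` to take plain (non-adaptive) gradient
    steps at its learning rate instead — used for the filter parameters,
    whose large rate would otherwise turn Adam's unit-scale normalized steps
    into a random walk across the frequency axis.
    """

    def __init__(self, groups: list[dict], betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = []
        for g in groups:
            params = list(g["params"])
            self.groups.append({
                "params": params,
                "lr": float(g["lr"]),
                "algo": g.get("algo", "adam"),
                "m": [np.zeros_like(p.data) for p in params],
                "v": [np.zeros_like(p.data) for p in params],
            })
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for g in self.groups:
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                if g["algo"] == "sgd":
                    p.data -= g["lr"] * p.grad
                    continue
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad ** 2
                p.data -= g["lr"] * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
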