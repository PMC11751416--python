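"""Neural-network layers built on the autograd engine.

Initialisation is driven by an explicit :class:`numpy.random.Generator` so
that model construction is reproducible from a single seed. Layers follow the
train/eval convention of the larger deep-learning frameworks: dropout and
batch-norm statistics behave differently under :meth:`Module.train` and
:meth:`Module.eval`.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Conv1d", "BatchNorm1d", "Linear", "Dropout", "ReLU",
    "Sequential", "hybrid_pool",
]

_DTYPE = np.float32


class Module:
    """Base class: parameter registry plus a train/eval mode flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out = {}
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self.buffers()
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value).copy()
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unknown parameter {key!r}")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Module):
    """1-D convolution with He-normal init; supports stride, dilation and
    asymmetric (causal) padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | tuple[int, int] = 0, dilation: int = 1,
                 bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale,
                                        (out_channels, in_channels, kernel_size)
                                        ).astype(_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=_DTYPE),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, time) for (N, C, L) input.

    Training mode normalises with batch statistics and updates running
    moments; eval mode uses the stored moments, making inference
    deterministic and batch-independent.
    """

    def __init__(self, num_channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones((1, num_channels, 1), dtype=_DTYPE),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_channels, 1), dtype=_DTYPE),
                           requires_grad=True)
        self.running_mean = np.zeros((1, num_channels, 1), dtype=_DTYPE)
        self.running_var = np.ones((1, num_channels, 1), dtype=_DTYPE)

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {prefix + "running_mean": self.running_mean,
                prefix + "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.astype(_DTYPE))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.astype(_DTYPE))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)
                                        ).astype(_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=_DTYPE),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Masks come from a dedicated
    generator so the data order alone determines them for a fixed seed."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * mask


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._order = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._order:
            x = m(x)
        return x


def hybrid_pool(feature_map: Tensor | np.ndarray) -> Tensor:
    """Global max- and average-pooling over time, concatenated.

    Accepts (N, C, T) or (C, T); returns (N, 2C) or (2C,). The max half
    occupies the first C entries, the mean half the last C.
    """
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    squeeze = x.ndim == 2
    if squeeze:
        x = x.reshape(1, *x.shape)
    if x.shape[-1] < 1:
        raise ValueError("hybrid_pool requires a nonempty time axis")
    pooled = concat([x.max(axis=2), x.mean(axis=2)], axis=1)
    return pooled.reshape(pooled.shape[1]) if squeeze else pooled
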