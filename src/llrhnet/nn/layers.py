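"""Layer/module abstractions over the autodiff core.

Modules register parameters and sub-modules automatically via attribute
assignment, expose ``parameters()`` / ``named_parameters()`` / ``state_dict``
and a train/eval switch, and are all constructed from an explicit
``numpy.random.Generator`` so that weight initialisation is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    batch_norm,
    batch_norm_train,
    conv2d,
    dropout,
    layer_norm,
)

DTYPE = np.float32


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        """Total number of trainable scalars."""
        return sum(p.data.size for p in self.parameters())

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, m in self._modules.items():
            yield from m.named_modules(prefix=f"{prefix}{name}.")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for prefix, m in self.named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                key = f"{prefix}.{bname}" if prefix else bname
                state[key] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for prefix, m in self.named_modules():
            for bname in getattr(m, "_buffers", {}):
                key = f"{prefix}.{bname}" if prefix else bname
                m._buffers[bname] = state[key].astype(m._buffers[bname].dtype).copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _param(array: np.ndarray) -> Tensor:
    return Tensor(array.astype(DTYPE), requires_grad=True)


class Conv2d(Module):
    """2D convolution; He-normal weight init, zero bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = _param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = _param(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=DTYPE),
            "running_var": np.ones(channels, dtype=DTYPE),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            flat = x.data.reshape(x.data.shape[0], x.data.shape[1], -1)
            mean = flat.mean(axis=(0, 2))
            var = flat.var(axis=(0, 2))
            m = self.momentum
            self._buffers["running_mean"] = ((1 - m) * self._buffers["running_mean"]
                                             + m * mean).astype(DTYPE)
            self._buffers["running_var"] = ((1 - m) * self._buffers["running_var"]
                                            + m * var).astype(DTYPE)
            return batch_norm_train(x, self.gamma, self.beta, self.eps,
                                    stats=(mean, var))
        return batch_norm(x, self.gamma, self.beta,
                          self._buffers["running_mean"], self._buffers["running_var"],
                          self.eps)


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = _param(np.ones(width))
        self.beta = _param(np.zeros(width))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    """Affine map on the last axis; Xavier-uniform init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = _param(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = _param(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        return dropout(x, self.rate, self.rng)
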