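"""Neural-network building blocks over the autograd tensors.

Follows the torch.nn naming conventions (Module/Parameter, train/eval,
state_dict) so the network code reads like standard segmentation code, but
everything runs on NumPy.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2x2, maxpool2x2

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "ConvTranspose2x2",
    "BatchNorm2d", "ReLU", "Sigmoid", "Linear", "MaxPool2x2",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter/buffer discovery via attribute walking."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- registry ------------------------------------------------------
    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float32)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_buffers(self, prefix: str = ""):
        for name, val in self._buffers.items():
            yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buffer:" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, val in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                owner, _, leaf = self._resolve_buffer(name)
                owner._buffers[leaf] = np.asarray(val, dtype=np.float32).copy()
            else:
                params[key].data = np.asarray(val, dtype=np.float32).copy()

    def _resolve_buffer(self, dotted: str):
        parts = dotted.split(".")
        owner: Module = self
        i = 0
        while i < len(parts) - 1:
            attr = getattr(owner, parts[i])
            if isinstance(attr, (list, tuple)):
                attr = attr[int(parts[i + 1])]
                i += 1
            owner = attr
            i += 1
        return owner, dotted, parts[-1]

    # -- mode ----------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    """Stride-1 'same'-padded grouped convolution with He initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, groups: int = 1, bias: bool = True):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(
                f"channels ({in_ch}->{out_ch}) not divisible by groups={groups}"
            )
        fan_in = (in_ch // groups) * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.standard_normal((out_ch, in_ch // groups, kernel, kernel)) * std
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.kernel = kernel
        self.groups = groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, padding=self.kernel // 2,
                      groups=self.groups)


class ConvTranspose2x2(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_ch)
        self.weight = Parameter(rng.standard_normal((in_ch, out_ch, 2, 2)) * std)
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))

    def forward(self, x: Tensor):
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            ).astype(np.float32)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            ).astype(np.float32)
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
            xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2x2(Module):
    def forward(self, x):
        return maxpool2x2(x)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.standard_normal((in_f, out_f)) * std)
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x):
        return x @ self.weight + self.bias
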