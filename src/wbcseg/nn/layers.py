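"""Layer/module containers over the autograd primitives."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

# module-level rng used only for constructor-time default initialization;
# builders re-initialize deterministically via init_parameters(seed=...)
_ctor_rng = np.random.default_rng(0x5EED)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight container tracking parameters, buffers and submodules."""

    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                sub = f"{prefix}.{name}" if prefix else name
                yield from val.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state --------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                key = f"{mname}.{bname}" if mname else bname
                state[key] = buf.copy()
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        buffers = {}
        for mname, m in self.named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                buffers[f"{mname}.{bname}" if mname else bname] = buf
        for key, arr in state.items():
            if key in own:
                if own[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{own[key].data.shape} vs {arr.shape}")
                own[key].data = np.asarray(arr, dtype=np.float32).copy()
            elif key in buffers:
                buffers[key][...] = arr
            else:
                raise KeyError(f"unknown state entry {key!r}")
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)

    def __iter__(self):
        i = 0
        while hasattr(self, str(i)):
            yield getattr(self, str(i))
            i += 1

    def __getitem__(self, i):
        return getattr(self, str(i))

    def __len__(self):
        return sum(1 for _ in self)

    def append(self, m: Module):
        setattr(self, str(len(self)), m)


def _he_normal(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Square-kernel 2-D convolution; ``padding=None`` preserves spatial
    size at stride 1 (padding = (k-1)*dilation // 2, odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        if min(in_channels, out_channels, kernel_size, stride, dilation) < 1:
            raise ValueError("Conv2d arguments must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.padding = ((kernel_size - 1) * dilation) // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_normal(
            _ctor_rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self._buffers = {
            "running_mean": np.zeros(num_features, np.float32),
            "running_var": np.ones(num_features, np.float32),
        }

    def forward(self, x):
        return ag.batch_norm2d(x, self.weight, self.bias,
                               self._buffers["running_mean"],
                               self._buffers["running_var"],
                               training=self.training,
                               momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_he_normal(
            _ctor_rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ag.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return ag.upsample_bilinear2x(x)


def init_parameters(module: Module, seed: int = 0) -> Module:
    """Deterministic re-initialization: He fan-in for conv/linear weights,
    zero biases, unit BN scale / zero shift, reset running statistics."""
    rng = np.random.default_rng(seed)
    for _, m in module.named_modules():
        if isinstance(m, Conv2d):
            fan_in = m.in_channels * m.kernel_size ** 2
            m.weight.data = _he_normal(rng, m.weight.data.shape, fan_in)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, Linear):
            m.weight.data = _he_normal(rng, m.weight.data.shape, m.in_features)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, BatchNorm2d):
            m.weight.data = np.ones_like(m.weight.data)
            m.bias.data = np.zeros_like(m.bias.data)
            m._buffers["running_mean"][...] = 0.0
            m._buffers["running_var"][...] = 1.0
    return module


def parameter_count(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())
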