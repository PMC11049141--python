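"""Neural-network layers, parameter management and optimisation.

Layers are thin stateful wrappers over the :mod:`pisnet.autodiff`
primitives.  A :class:`Module` discovers parameters and submodules by
attribute introspection, so ``model.named_parameters()`` enumerates every
trainable array — the parameter counter and the checkpoint format both rely
on that enumeration being exhaustive.
"""
from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "ModuleList", "Parameter", "Conv2d", "DepthwiseConv2d",
    "ChannelLinear", "LayerNorm", "BatchNorm2d", "MaxPool2d", "Adam",
    "cosine_annealing_lr", "seed_all",
]

_GLOBAL_RNG = np.random.default_rng(0)


def seed_all(seed):
    """Reset the generator used for parameter initialisation."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def Parameter(data):
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def _kaiming_uniform(shape, fan_in, a=math.sqrt(5)):
    gain = math.sqrt(2.0 / (1 + a * a))
    bound = gain * math.sqrt(3.0 / fan_in)
    return _GLOBAL_RNG.uniform(-bound, bound, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, sub in enumerate(val):
                    yield f"{name}.{i}", sub

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield (f"{prefix}{name}", val)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and not val.requires_grad:
                yield (f"{prefix}{name}", val)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def train(self, mode=True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.data.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(unexpected)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = np.asarray(arr, dtype=np.float32).copy()


class ModuleList(list):
    pass


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size,
                 stride=1, padding=0, groups=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        self.weight = Parameter(
            _kaiming_uniform((out_channels, in_channels // groups, k, k), fan_in))
        if bias:
            bound = 1.0 / math.sqrt(fan_in)
            self.bias = Parameter(
                _GLOBAL_RNG.uniform(-bound, bound, size=out_channels))
        else:
            self.bias = None

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, self.stride,
                        self.padding, self.groups)


class DepthwiseConv2d(Conv2d):
    """One independent spatial kernel per channel (implicit position code)."""

    def __init__(self, channels, kernel_size=3, bias=True):
        super().__init__(channels, channels, kernel_size,
                         padding=kernel_size // 2, groups=channels, bias=bias)


class ChannelLinear(Module):
    """Linear map over the channel axis of token maps — a 1x1 convolution.

    Weight shape (out, in, 1, 1); parameter count out*in + out, identical to
    a dense layer applied to (N_tokens, C) rows.
    """

    def __init__(self, in_channels, out_channels, bias=True):
        super().__init__()
        self.weight = Parameter(
            _kaiming_uniform((out_channels, in_channels, 1, 1), in_channels))
        if bias:
            bound = 1.0 / math.sqrt(in_channels)
            self.bias = Parameter(
                _GLOBAL_RNG.uniform(-bound, bound, size=out_channels))
        else:
            self.bias = None

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, 1, 0, 1)


class LayerNorm(Module):
    """Normalise across channels independently at every spatial location."""

    def __init__(self, channels, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xn * w + b


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = Tensor(np.zeros(channels, dtype=np.float32))
        self.running_var = Tensor(np.ones(channels, dtype=np.float32))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True) \
                  .mean(axis=3, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True) \
                .mean(axis=2, keepdims=True).mean(axis=3, keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean.data = ((1 - self.momentum) * self.running_mean.data
                                      + self.momentum * mu.data.ravel())
            self.running_var.data = ((1 - self.momentum) * self.running_var.data
                                     + self.momentum * unbiased)
            xn = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.data[None, :, None, None]
            sd = np.sqrt(self.running_var.data[None, :, None, None] + self.eps)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xn * w + b


class MaxPool2d(Module):
    def __init__(self, kernel, stride=None, padding=0):
        super().__init__()
        self.kernel = kernel
        self.stride = kernel if stride is None else stride
        self.padding = padding

    def forward(self, x):
        return x.maxpool2d(self.kernel, self.stride, self.padding)


class Adam:
    """Adam with the first-moment coefficient exposed as the momentum knob."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_annealing_lr(epoch, total_epochs, lr_max=1e-4, lr_min=1e-5):
    """Cosine decay from lr_max at epoch 0 to lr_min at the final epoch."""
    if total_epochs <= 1:
        return lr_max
    frac = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * frac))
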