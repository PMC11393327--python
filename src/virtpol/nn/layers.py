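"""Parameterised layers built on the autograd ops."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters through attribute assignment."""

    def parameters(self):
        params = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        """Flat list of parameter ndarrays, in a stable traversal order."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state mismatch: {len(arrays)} arrays for {len(params)} params")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"param shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, pad=None, rng=None, zero_init=False):
        if pad is None:
            pad = kernel // 2
        self.stride = stride
        self.pad = pad
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / fan_in)
            w = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * std).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_f, out_f, rng):
        std = np.sqrt(2.0 / in_f)
        self.weight = Tensor((rng.standard_normal((in_f, out_f)) * std).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class ResBlock3(Module):
    """Three 3x3 convolutions with a 1x1 convolutional residual path.

    Leaky-ReLU between convolutions and after the residual sum.
    """

    def __init__(self, in_ch, out_ch, rng, slope=0.1):
        self.slope = slope
        self.c1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.c3 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.proj = Conv2d(in_ch, out_ch, 1, pad=0, rng=rng)

    def forward(self, x):
        y = ag.leaky_relu(self.c1(x), self.slope)
        y = ag.leaky_relu(self.c2(y), self.slope)
        y = self.c3(y)
        return ag.leaky_relu(ag.add(y, self.proj(x)), self.slope)


class ResBlock2Down(Module):
    """Two-conv residual block; second conv has stride 2 (used by the critic)."""

    def __init__(self, in_ch, out_ch, rng, slope=0.1):
        self.slope = slope
        self.c1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, stride=2, rng=rng)
        self.proj = Conv2d(in_ch, out_ch, 1, stride=2, pad=0, rng=rng)

    def forward(self, x):
        y = ag.leaky_relu(self.c1(x), self.slope)
        y = self.c2(y)
        return ag.leaky_relu(ag.add(y, self.proj(x)), self.slope)


class AttentionGate(Module):
    """Additive attention gate: project skip and gating features to a shared
    width, ReLU, 1-channel conv + sigmoid, multiply onto the skip."""

    def __init__(self, skip_ch, gate_ch, rng):
        inter = max(skip_ch // 2, 1)
        self.theta = Conv2d(skip_ch, inter, 1, pad=0, rng=rng)
        self.phi = Conv2d(gate_ch, inter, 1, pad=0, rng=rng)
        self.psi = Conv2d(inter, 1, 1, pad=0, rng=rng)
        # start with gates open so skip features flow from step 0
        self.psi.bias.data[:] = 2.0

    def forward(self, skip, gate):
        a = ag.relu(ag.add(self.theta(skip), self.phi(gate)))
        w = ag.sigmoid(self.psi(a))
        return ag.mul(skip, w)


class Adam(Module):
    """Adam with the conventional (0.9, 0.999) betas."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def parameters(self):  # not trainable itself
        return []

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
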