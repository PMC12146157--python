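"""Neural-network building blocks on the autograd engine.

Provides the module/parameter machinery plus the layers the detector is
assembled from: plain zero-padded convolutions, snake convolutions whose
taps ride on learnable perpendicular offsets, batch normalisation, the
C2f split/bottleneck/merge block, and an Adam optimiser.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, conv2d, shift_sample

__all__ = [
    "Module", "Conv2d", "SnakeConv2d", "BatchNorm2d", "ConvBlock",
    "Bottleneck", "C2f", "Adam", "snake_conv2d",
]


class Module:
    """Container with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (prefix + name, value)
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def apply_constraints(self):
        """Re-impose per-layer parameter constraints after an update."""
        for _, child in self._children():
            child.apply_constraints()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- checkpoint plumbing ------------------------------------------
    def _buffers(self) -> dict:
        return {}

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[prefix + name] = value.data.copy()
        for k, v in self._buffers().items():
            out[prefix + k] = np.array(v, copy=True)
        for name, child in self._children():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                value.data[...] = state[name]
        for k in self._buffers():
            getattr(self, k)[...] = state[k]
        for name, child in self._children():
            sub = {key[len(name) + 1:]: v for key, v in state.items()
                   if key.startswith(name + ".")}
            child.load_state_dict(sub)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2
        self.weight = _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)

    __call__ = forward


def snake_conv2d(x: Tensor, weight: Tensor, offsets: Tensor, axis: str) -> Tensor:
    """Serpentine convolution: k taps along ``axis`` with learnable
    perpendicular displacements, sampled bilinearly with zero padding.

    weight: (Co, Ci, k); offsets: (k,).  Tap c of a horizontal kernel
    samples (x_i + c, y_i + dy_c); a vertical kernel swaps the roles.
    """
    co, ci, k = weight.shape
    half = k // 2
    n, _, h, w = x.shape
    out = None
    for idx in range(k):
        c = idx - half
        d = offsets[idx]                      # scalar tensor
        i0 = int(np.floor(float(d.data)))
        f = d - float(i0)                     # fractional part, differentiable
        if axis == "horizontal":              # taps spread in x, offset in y
            s0 = shift_sample(x, i0, c)
            s1 = shift_sample(x, i0 + 1, c)
        elif axis == "vertical":              # taps spread in y, offset in x
            s0 = shift_sample(x, c, i0)
            s1 = shift_sample(x, c, i0 + 1)
        else:
            raise ValueError(f"unknown snake axis: {axis!r}")
        samp = s0 + (s1 - s0) * f
        wc = weight[:, :, idx]                # (Co, Ci)
        tap = (wc @ samp.reshape(n, ci, h * w)).reshape(n, co, h, w)
        out = tap if out is None else out + tap
    return out


class SnakeConv2d(Module):
    """Stride-1 snake convolution with per-tap learnable offsets.

    Offsets are shared across channels and clamped to ``offset_clamp``
    after every optimiser step.
    """

    def __init__(self, cin: int, cout: int, k: int = 3,
                 axis: str = "horizontal", offset_clamp: float = 1.0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("snake kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.axis = axis
        self.offset_clamp = float(offset_clamp)
        self.weight = _he_init(rng, (cout, cin, k), cin * k)
        self.offsets = Tensor(np.zeros(k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = snake_conv2d(x, self.weight, self.offsets, self.axis)
        if self.bias is not None:
            co = self.bias.shape[0]
            y = y + self.bias.reshape(1, co, 1, 1)
        return y

    __call__ = forward

    def apply_constraints(self):
        np.clip(self.offsets.data, -self.offset_clamp, self.offset_clamp,
                out=self.offsets.data)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        c = self.gamma.shape[0]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(c))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(c))
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - mu) / sd
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)

    __call__ = forward


class ConvBlock(Module):
    """Conv (plain or snake) -> BatchNorm -> SiLU."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 snake: bool = False, axis: str = "horizontal",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if snake:
            if stride != 1:
                raise ValueError("snake convolutions are stride-1")
            self.conv = SnakeConv2d(cin, cout, k=k, axis=axis, rng=rng, bias=False)
        else:
            self.conv = Conv2d(cin, cout, k=k, stride=stride, rng=rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()

    __call__ = forward


class Bottleneck(Module):
    """Two 3x3 convolutions with a residual add when shapes permit.

    With ``snake=True`` this is the serpentine variant: the two
    convolutions use perpendicular snake axes so offsets can bend the
    receptive field in both directions.
    """

    def __init__(self, cin: int, cout: int, snake: bool = False,
                 shortcut: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.add = shortcut and cin == cout
        self.cv1 = ConvBlock(cin, cout, 3, snake=snake, axis="horizontal", rng=rng)
        self.cv2 = ConvBlock(cout, cout, 3, snake=snake, axis="vertical", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    __call__ = forward


class C2f(Module):
    """Split -> n bottlenecks (each appended) -> concatenate -> project.

    With ``snake=True`` the bottleneck convolutions and the pre/post
    channel-adjust convolutions are all snake-kernel instances (the
    channel adjusters use a single-tap snake kernel, i.e. a 1x1
    convolution with a learnable sub-pixel shift).
    """

    def __init__(self, cin: int, cout: int, n: int = 1, snake: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.mid = max(cout // 2, 1)
        self.cv_pre = ConvBlock(cin, 2 * self.mid, k=1, snake=snake, rng=rng)
        self.blocks = [Bottleneck(self.mid, self.mid, snake=snake, rng=rng)
                       for _ in range(n)]
        self.cv_post = ConvBlock((2 + n) * self.mid, cout, k=1, snake=snake, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv_pre(x)
        a = y[:, : self.mid]
        b = y[:, self.mid:]
        outs = [a, b]
        cur = b
        for blk in self.blocks:
            cur = blk(cur)
            outs.append(cur)
        return self.cv_post(concatenate(outs, axis=1))

    __call__ = forward


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
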