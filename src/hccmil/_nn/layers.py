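"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _accumulate, make
from . import ops


class Module:
    """Base class: tracks child modules and parameters by attribute order."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for n, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out.append((prefix + n, v))
        for mn, m in self._modules.items():
            out.extend(m.buffers(prefix + mn + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # --- flat serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.buffers():
            d["buf:" + n] = b.copy()
        return d

    def load_state_dict(self, d: dict) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(d[n], dtype=np.float32).reshape(p.data.shape)
        for n, _ in self.buffers():
            obj, attr = self._resolve(n)
            setattr(obj, attr, np.asarray(d["buf:" + n], dtype=np.float32))

    def _resolve(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj._modules[part] if part in obj._modules else getattr(obj, part)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """Kaiming-normal initialized parameter."""
    std = np.sqrt(2.0 / fan_in)
    t = Tensor(rng.normal(0.0, std, size=shape).astype(np.float32))
    t.requires_grad = True
    return t


def _zeros(shape) -> Tensor:
    t = Tensor(np.zeros(shape, dtype=np.float32))
    t.requires_grad = True
    return t


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, k=3, stride=1, padding=None,
                 depthwise=False, bias=True):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.depthwise = depthwise
        if depthwise:
            self.weight = _param(rng, (in_ch, 1, k, k), fan_in=k * k)
        else:
            self.weight = _param(rng, (out_ch, in_ch, k, k), fan_in=in_ch * k * k)
        self.bias = _zeros(out_ch if not depthwise else in_ch) if bias else None

    def forward(self, x):
        return ops.conv2d(x, self.weight, self.bias, stride=self.stride,
                          padding=self.padding, depthwise=self.depthwise)


class BatchNorm2d(Module):
    """Per-channel batch normalization (NCHW); running stats for inference."""

    def __init__(self, n_ch, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = _zeros(n_ch)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if self.training:
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * v).astype(np.float32)
        else:
            m, v = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(v + eps)
        xhat = (x.data - m[None, :, None, None]) * inv_std[None, :, None, None]
        out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
            gxh = g * gamma.data[None, :, None, None]
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv_std[None, :, None, None] / n) * (n * gxh - s1 - xhat * s2)
            else:
                gx = gxh * inv_std[None, :, None, None]
            _accumulate(x, gx.astype(np.float32))

        return make(out_data.astype(np.float32), (x, gamma, beta), backward)


class GroupNorm2d(Module):
    """Group normalization over (channel-group, H, W) per sample.

    Batch-independent, so training and inference are identical — the right
    normalizer when optimizing one bag of tiles at a time, where batch
    statistics would couple the instances of a bag.
    """

    def __init__(self, n_ch, n_groups=None, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.groups = min(n_groups or max(n_ch // 4, 1), n_ch)
        if n_ch % self.groups:
            self.groups = 1
        self.gamma = Tensor(np.ones(n_ch, dtype=np.float32), requires_grad=True)
        self.beta = _zeros(n_ch)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        N, C, H, W = x.data.shape
        G = self.groups
        xg = x.data.reshape(N, G, C // G * H * W)
        m = xg.mean(axis=2, keepdims=True)
        v = xg.var(axis=2, keepdims=True)
        inv_std = 1.0 / np.sqrt(v + self.eps)
        xhat = ((xg - m) * inv_std).reshape(N, C, H, W)
        out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def backward(g):
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
            gxh = (g * gamma.data[None, :, None, None]).reshape(N, G, C // G * H * W)
            xh = xhat.reshape(N, G, C // G * H * W)
            n = C // G * H * W
            s1 = gxh.sum(axis=2, keepdims=True)
            s2 = (gxh * xh).sum(axis=2, keepdims=True)
            gx = (inv_std / n) * (n * gxh - s1 - xh * s2)
            _accumulate(x, gx.reshape(N, C, H, W).astype(np.float32))

        return make(out_data.astype(np.float32), (x, gamma, beta), backward)


class Linear(Module):
    def __init__(self, rng, in_f, out_f):
        super().__init__()
        self.weight = _param(rng, (in_f, out_f), fan_in=in_f)
        self.bias = _zeros(out_f)

    def forward(self, x):
        return ops.linear(x, self.weight, self.bias)


class Adam:
    """Adam optimizer; ``l2`` adds the gradient of l2 * sum(w^2), i.e. 2*l2*w."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, l2: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.l2:
                g = g + 2.0 * self.l2 * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
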