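"""Network building blocks (Module system, layers, initialisation).

Modules hold named Parameters and sub-modules; ``state_dict`` /
``load_state_dict`` round-trip weights bitwise (float64 throughout), which
is what makes checkpoint reload reproduce outputs exactly.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container with named parameters, buffers and sub-modules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, p in self._params.items():
            state[prefix + k] = p.data
        for k, b in self._buffers.items():
            state[prefix + k] = b
        for k, m in self._modules.items():
            state.update(m.named_state(prefix + k + "."))
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)} extra={sorted(extra)}")
        for k, arr in state.items():
            tgt = own[k]
            if tgt.shape != np.asarray(arr).shape:
                raise ValueError(f"shape mismatch for {k}")
            tgt[...] = arr

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module) -> None:
        idx = len(self._list)
        self._list.append(m)
        self._modules[str(idx)] = m
        object.__setattr__(self, str(idx), m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Same-padded 2-D convolution; odd square kernel, optional dilation."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """2x spatial upsampling via a stride-2, 2x2-kernel transposed convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (c_in, c_out, 2, 2), c_in * 4))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2x2(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W) with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.reshape(-1)
            self.running_var *= 1 - m
            self.running_var += m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xc / (var + self.eps).sqrt() * g + b


def sinusoidal_embedding(t, dim: int) -> np.ndarray:
    """Standard sinusoidal step embedding of dimension ``dim``.

    ``t`` may be a scalar (returns [dim]) or a length-N vector (returns
    [N, dim]).
    """
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    tarr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    ang = tarr[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], dim - emb.shape[1]))], axis=1)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return emb[0]
    return emb
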