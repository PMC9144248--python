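"""Layers for small segmentation conv-nets, built on the autodiff Tensor.

Parameters are initialized from N(0, sigma^2) with a caller-supplied
`numpy.random.Generator`, so identical (config, seed) always yields
identical weights.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "DoubleConv",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self):
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for c in self.children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # buffers (batch-norm running stats) are serialized alongside parameters
    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.array(value, dtype=params[name].dtype)
            else:
                self._set_buffer(name, np.array(value))

    def _set_buffer(self, dotted: str, value: np.ndarray):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            attr = getattr(obj, part, None)
            if attr is None and part.isdigit():
                raise KeyError(dotted)
            if isinstance(obj, (list, tuple)):
                obj = obj[int(part)]
            elif isinstance(attr, (list, tuple)):
                obj = attr
            else:
                obj = attr
        if isinstance(obj, (list, tuple)):
            raise KeyError(dotted)
        setattr(obj, parts[-1], value)


def _resolve(module: Module, dotted: str):
    obj = module
    for part in dotted.split("."):
        obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
    return obj


# patch _set_buffer with the list-aware resolver (keeps load_state_dict simple)
def _set_buffer(self: Module, dotted: str, value: np.ndarray):
    parts = dotted.split(".")
    owner = _resolve(self, ".".join(parts[:-1])) if len(parts) > 1 else self
    setattr(owner, parts[-1], value)


Module._set_buffer = _set_buffer


def _init_std(sigma, fan_in) -> float:
    """Fixed sigma, or He scaling (sqrt(2/fan_in)) when sigma == "he"."""
    if sigma == "he":
        return float(np.sqrt(2.0 / fan_in))
    return float(sigma)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, padding, rng, sigma=0.02, dtype=np.float32):
        super().__init__()
        self.padding = padding
        std = _init_std(sigma, cin * kernel * kernel)
        self.weight = Tensor(
            rng.normal(0.0, std, (cout, cin, kernel, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.padding)


class ConvTranspose2d(Module):
    """2x2 stride-2 learnable upsampling."""

    def __init__(self, cin, cout, rng, sigma=0.02, dtype=np.float32):
        super().__init__()
        # stride-2 2x2: each output pixel sees exactly one input position
        std = _init_std(sigma, cin)
        self.weight = Tensor(
            rng.normal(0.0, std, (cin, cout, 2, 2)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            out, mu, var = x.batchnorm(self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
            return out
        mu = self.running_mean.reshape(shape)
        std_inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
        xhat = (x - mu) * std_inv
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class DoubleConv(Module):
    """One encoder/decoder level: (conv3x3 -> [BN] -> ReLU) twice."""

    def __init__(self, cin, cout, rng, batch_norm=True, sigma=0.02, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, 1, rng, sigma, dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype) if batch_norm else None
        self.conv2 = Conv2d(cout, cout, 3, 1, rng, sigma, dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = x.relu()
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return x.relu()
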