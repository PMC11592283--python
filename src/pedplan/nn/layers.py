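"""Parameterized layers and a minimal Module container."""

from __future__ import annotations

import numpy as np

from pedplan.errors import ValidationError
from pedplan.nn import core
from pedplan.nn.core import Tensor


class Module:
    """Base class: parameter registry, train/eval mode, state (de)serialization."""

    def __init__(self) -> None:
        self.training = True

    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self) -> None:
        self.training = True
        for _, c in self.children():
            c.train()

    def eval(self) -> None:
        self.training = False
        for _, c in self.children():
            c.eval()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for cname, child in self.children():
            yield from child._named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b for n, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer:"):
                target = buffers.get(key[len("buffer:"):])
                if target is None:
                    raise ValidationError(f"unknown buffer {key!r} in checkpoint")
                target[...] = arr
            else:
                if key not in params:
                    raise ValidationError(f"unknown parameter {key!r} in checkpoint")
                if params[key].data.shape != arr.shape:
                    raise ValidationError(
                        f"shape mismatch for {key!r}: {params[key].data.shape} vs {arr.shape}"
                    )
                params[key].data = np.asarray(arr, dtype=np.float32)


def _param(shape, std: float, rng: np.random.Generator) -> Tensor:
    return Tensor(rng.standard_normal(shape).astype(np.float32) * std, requires_grad=True)


class Conv3d(Module):
    """'Same'-padded 3D convolution, kernel 1 or 3, He initialization."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator):
        super().__init__()
        if k not in (1, 3):
            raise ValidationError(f"kernel must be 1 or 3, got {k}")
        fan_in = cin * k**3
        self.w = _param((cout, cin, k, k, k), np.sqrt(2.0 / fan_in), rng)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv3d(x, self.w, self.b)


class ConvTranspose3d(Module):
    """Kernel-2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        super().__init__()
        self.w = _param((cin, cout, 2, 2, 2), np.sqrt(2.0 / (cin * 8)), rng)

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv_transpose2x(x, self.w)


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial axes.

    Training batches are single samples, so the batch statistics coincide
    with the sample's own spatial moments; inference normalizes by the same
    per-sample moments (running averages over deep single-sample stacks
    drift and would make train and eval behavior inconsistent).  Running
    statistics are still tracked as buffers for introspection.
    """

    def __init__(self, c: int, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        return core.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=True, momentum=self.momentum if self.training else 0.0,
        )
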