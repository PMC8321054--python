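"""Layer/module containers over the autodiff primitives."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from .functional import batch_norm3d, conv3d

__all__ = ["Module", "Conv3d", "BatchNorm3d"]


class Module:
    """Base class: tracks parameter tensors and child modules by attribute."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        """Exact count of trainable scalars."""
        return int(sum(p.data.size for p in self.parameters()))

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running-statistic arrays, in a stable order."""
        arrays: list[np.ndarray] = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    arrays.append(v.data)
            if isinstance(m, BatchNorm3d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match module structure")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("checkpoint array shape mismatch")
            dst[...] = src


class Conv3d(Module):
    """Same-padded stride-1 3D convolution, He-initialised."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size**3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels) + (kernel_size,) * 3),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm3d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )
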