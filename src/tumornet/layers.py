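"""Trainable layer primitives built on the autodiff engine.

Parameter-counting convention used throughout the package: every convolution
and dense layer carries a weight and a bias, and every batch-normalization
layer contributes four numbers per normalized channel — learnable scale and
shift plus the non-learnable running mean and running variance.  ``Module``
exposes both groups so that model totals can be audited tensor by tensor.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with recursive parameter/buffer registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _sync_buffer(self, name: str, value: np.ndarray) -> None:
        """Rebind a buffer after in-place-incompatible update."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def regularized(self) -> list[Tensor]:
        """Weight tensors subject to the L2 penalty (kernels, not biases/BN)."""
        out = []
        for name, p in self.named_parameters():
            if name.rsplit(".", 1)[-1] == "weight":
                out.append(p)
        return out

    def num_parameters(self) -> int:
        """Total size of all parameters plus running statistics."""
        total = sum(p.data.size for _, p in self.named_parameters())
        total += sum(b.size for _, b in self.named_buffers())
        return total

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as archive:
            state = dict(archive.items())
        for key, p in self.named_parameters():
            stored = state[f"param:{key}"]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint mismatch for {key}: stored {stored.shape}, "
                    f"model expects {p.data.shape}"
                )
            p.data = stored.astype(p.data.dtype)
        for key, _ in list(self.named_buffers()):
            self._assign_buffer(key, state[f"buffer:{key}"])

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod._sync_buffer(leaf, value.astype(np.float32))

    def __call__(self, x, *, training: bool = False, rng=None, **kwargs):
        return self.forward(x, training=training, rng=rng, **kwargs)

    def forward(self, x, *, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Variance-scaling (fan-in) normal initialization."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    """Stride-1 'same'-padded convolution with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x, *, training=False, rng=None):
        received = x.data.shape[1]
        if received != self.in_channels:
            raise ValueError(
                f"Conv2d expected {self.in_channels} input channels, received {received}"
            )
        return ad.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch moments and updates the running
    mean/variance with momentum; inference mode normalizes with the stored
    running statistics.  Four numbers per channel in the counting convention.

    The default momentum of 0.9 lets the running statistics converge within
    a few dozen updates, which matters for the small training runs this
    package is exercised with; neither momentum nor epsilon affects the
    parameter count.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x, *, training=False, rng=None):
        if training:
            out, batch_mean, batch_var = ad.batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean *= m
            self.running_mean += (1 - m) * batch_mean.astype(np.float32)
            self.running_var *= m
            self.running_var += (1 - m) * batch_var.astype(np.float32)
            return out
        return ad.batchnorm_infer(x, self.gamma, self.beta,
                                  self.running_mean, self.running_var, self.eps)


class Dense(Module):
    """Fully connected layer on (batch, features) inputs."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(he_normal(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x, *, training=False, rng=None):
        return ad.add(ad.matmul(x, self.weight), self.bias)
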