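"""Residual convolutional block: 3x3 conv -> BN -> ReLU -> 1x1 conv -> BN,
merged with a (possibly projected) shortcut by elementwise addition and a
final ReLU.

When the input and output channel counts differ the shortcut is a 1x1
convolution followed by BN (a projection shortcut); when they match the
shortcut is the identity.  All convolutions use stride 1, "same" padding and
carry bias terms, and their kernels are subject to the L2 penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .layers import BatchNorm2d, Conv2d, Module


@dataclass
class ConvBlockSpec:
    in_channels: int
    filters: int
    stride: int = 1
    l2_lambda: float = 1e-3

    def __post_init__(self):
        if self.in_channels < 1 or self.filters < 1:
            raise ValueError("in_channels and filters must be >= 1")
        if self.stride != 1:
            raise ValueError("only stride 1 is used in this architecture")


class ConvBlock(Module):
    def __init__(self, spec: ConvBlockSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.conv3 = Conv2d(spec.in_channels, spec.filters, 3, rng)
        self.bn1 = BatchNorm2d(spec.filters)
        self.conv1 = Conv2d(spec.filters, spec.filters, 1, rng)
        self.bn2 = BatchNorm2d(spec.filters)
        self.has_projection = spec.in_channels != spec.filters
        if self.has_projection:
            self.proj = Conv2d(spec.in_channels, spec.filters, 1, rng)
            self.bn_proj = BatchNorm2d(spec.filters)

    def forward(self, x, *, training=False, rng=None):
        received = x.data.shape[1]
        if received != self.spec.in_channels:
            raise ValueError(
                f"conv block expected {self.spec.in_channels} channels, received {received}"
            )
        h = self.conv3(x, training=training)
        h = self.bn1(h, training=training)
        h = ad.relu(h)
        h = self.conv1(h, training=training)
        h = self.bn2(h, training=training)
        if self.has_projection:
            shortcut = self.bn_proj(self.proj(x, training=training), training=training)
        else:
            shortcut = x
        return ad.relu(ad.add(h, shortcut))


def conv_block_param_count(spec: ConvBlockSpec) -> int:
    """Closed-form parameter total for one block.

    Counts weights and biases of both main-path convolutions, four numbers per
    BN channel, and the projection conv + BN only on channel mismatch:
    f * (10*in + f + 15) with a projection, 10 * f * (f + 1) without.
    """
    c_in, f = spec.in_channels, spec.filters
    if c_in != f:
        return f * (10 * c_in + f + 15)
    return 10 * f * (f + 1)
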