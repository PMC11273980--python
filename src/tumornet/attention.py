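"""Hybrid channel + spatial attention.

Channel attention reduces the feature map to C/ratio channels, pools it
globally by both average and max, and maps the concatenated statistics
through a 1x1 convolution and a sigmoid into one gate value per channel.
Spatial attention condenses the gated map to a single channel, looks at it
through 3x3 and 5x5 convolutions, and fuses them into a sigmoid gate per
spatial position.  Each gate is applied residually (F + F*gate), and the
module's output is recombined with the original input by a final addition:

    F'  = F + F * S        (channel gate S, one scalar per channel)
    F'' = F' + F' * A      (spatial gate A, one map shared by all channels)
    out = F + F''

With all convolution weights and biases zero and BN at its initialization
state both gates are exactly 0.5, so the module reduces to out = 3.25 * F —
a closed form the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .layers import BatchNorm2d, Conv2d, Module


@dataclass
class AttentionSpec:
    channels: int
    ratio: int = 2

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")

    @property
    def reduced_channels(self) -> int:
        return max(self.channels // self.ratio, 1)


@dataclass
class AttentionTrace:
    """Every intermediate of the hybrid attention forward pass.

    Arrays carry a leading batch axis; for a single image the shapes are those
    listed (FR: (Cr,H,W), S: (C,1,1), A: (1,H,W), ...).
    """

    FR: np.ndarray | None = None
    Aavg: np.ndarray | None = None
    Amax: np.ndarray | None = None
    AF: np.ndarray | None = None
    S: np.ndarray | None = None
    Fprime: np.ndarray | None = None
    FC: np.ndarray | None = None
    C1: np.ndarray | None = None
    C2: np.ndarray | None = None
    A: np.ndarray | None = None
    Fdprime: np.ndarray | None = None


class ChannelAttention(Module):
    """Per-channel sigmoid gate from dual-pooled reduced features."""

    def __init__(self, spec: AttentionSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        cr = spec.reduced_channels
        self.reduce = Conv2d(spec.channels, cr, 1, rng)
        self.bn = BatchNorm2d(cr)
        self.scale = Conv2d(2 * cr, spec.channels, 1, rng)

    def forward(self, x, *, training=False, rng=None, trace: AttentionTrace | None = None):
        received = x.data.shape[1]
        if received != self.spec.channels:
            raise ValueError(
                f"channel attention expected {self.spec.channels} channels, received {received}"
            )
        fr = ad.relu(self.bn(self.reduce(x, training=training), training=training))
        a_avg = ad.mean(fr, axis=(2, 3), keepdims=True)           # (N, Cr, 1, 1)
        a_max = ad.reduce_max(fr, axis=(2, 3), keepdims=True)     # (N, Cr, 1, 1)
        af = ad.concat([a_avg, a_max], axis=1)                    # (N, 2Cr, 1, 1)
        s = ad.sigmoid(self.scale(af, training=training))         # (N, C, 1, 1)
        fprime = ad.add(x, ad.mul(x, s))
        if trace is not None:
            trace.FR = fr.data
            trace.Aavg = a_avg.data.reshape(a_avg.data.shape[:2])
            trace.Amax = a_max.data.reshape(a_max.data.shape[:2])
            trace.AF = af.data
            trace.S = s.data
            trace.Fprime = fprime.data
        return fprime


class SpatialAttention(Module):
    """Per-position sigmoid gate from multi-scale views of a condensed map."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.condense = Conv2d(channels, 1, 1, rng)
        self.bn = BatchNorm2d(1)
        self.conv3 = Conv2d(1, 1, 3, rng)
        self.conv5 = Conv2d(1, 1, 5, rng)
        self.fuse = Conv2d(2, 1, 3, rng)

    def forward(self, x, *, training=False, rng=None, trace: AttentionTrace | None = None):
        fc = ad.relu(self.bn(self.condense(x, training=training), training=training))
        c1 = self.conv3(fc, training=training)
        c2 = self.conv5(fc, training=training)
        a = ad.sigmoid(self.fuse(ad.concat([c1, c2], axis=1), training=training))
        fdprime = ad.add(x, ad.mul(x, a))
        if trace is not None:
            trace.FC = fc.data
            trace.C1 = c1.data
            trace.C2 = c2.data
            trace.A = a.data
            trace.Fdprime = fdprime.data
        return fdprime


class HybridAttention(Module):
    """Channel gate, then spatial gate, then recombination with the input."""

    def __init__(self, spec: AttentionSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.channel = ChannelAttention(spec, rng)
        self.spatial = SpatialAttention(spec.channels, rng)

    def forward(self, x, *, training=False, rng=None):
        out, _ = self.forward_with_trace(x, training=training)
        return out

    def forward_with_trace(self, x, *, training=False):
        trace = AttentionTrace()
        fprime = self.channel(x, training=training, trace=trace)
        fdprime = self.spatial(fprime, training=training, trace=trace)
        return ad.add(x, fdprime), trace


def attention_param_count(spec: AttentionSpec) -> int:
    """Closed-form parameter total of one hybrid attention module.

    Sums the reduce conv (C*Cr + Cr) and its BN (4*Cr), the scale conv
    (2*Cr*C + C), the condense conv (C + 1) and its BN (4), the fixed-size
    3x3 (10), 5x5 (26) and fusion (19) convolutions.  For even C at ratio 2
    this equals 1.5*C^2 + 4.5*C + 60.
    """
    c, cr = spec.channels, spec.reduced_channels
    reduce_conv = c * cr + cr
    reduce_bn = 4 * cr
    scale_conv = 2 * cr * c + c
    condense_conv = c + 1
    condense_bn = 4
    return reduce_conv + reduce_bn + scale_conv + condense_conv + condense_bn + 10 + 26 + 19
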