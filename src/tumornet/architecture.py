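"""Full classifier assembly and exact parameter accounting.

The network is a stack of residual conv blocks with widths
16, 32, 64, 128, 128, 256 (2x2 stride-2 max-pooling after blocks 1-4 and 6),
one hybrid attention module on the final 256-channel map, then global average
pooling, a 512-unit ReLU dense layer with dropout 0.5, and a 4-way softmax
classifier.  Under the counting convention of :mod:`tumornet.layers` the
totals are 829,172 parameters without the attention module and 928,688 with
it; ``count_parameters`` reproduces these by enumerating every tensor of an
instantiated model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .attention import AttentionSpec, HybridAttention, attention_param_count
from .conv_block import ConvBlock, ConvBlockSpec
from .layers import Dense, Module
from .nn_math import softmax

DEFAULT_BLOCK_FILTERS = (16, 32, 64, 128, 128, 256)
DEFAULT_POOL_AFTER = frozenset({1, 2, 3, 4, 6})


@dataclass
class ArchitectureSpec:
    """Declarative description of the classifier; the single source of truth
    for both model building and parameter accounting."""

    input_shape: tuple[int, int, int] = (3, 224, 224)
    block_filters: tuple[int, ...] = DEFAULT_BLOCK_FILTERS
    pool_after: frozenset[int] = DEFAULT_POOL_AFTER  # 1-based block indices
    attention_after_final_pool: bool = True
    attention_ratio: int = 2
    head_width: int = 512
    dropout_rate: float = 0.5
    num_classes: int = 4
    l2_lambda: float = 1e-3

    def __post_init__(self):
        self.block_filters = tuple(self.block_filters)
        self.pool_after = frozenset(self.pool_after)
        if not self.block_filters or any(f < 1 for f in self.block_filters):
            raise ValueError("block_filters must be a non-empty sequence of positive widths")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        _, h, w = self.input_shape
        if len(self.pool_after) > np.log2(min(h, w)):
            raise ValueError(
                f"{len(self.pool_after)} pools underflow a {h}x{w} input"
            )
        if any(i < 1 or i > len(self.block_filters) for i in self.pool_after):
            raise ValueError("pool_after indices must reference existing blocks (1-based)")

    def to_json(self) -> str:
        d = asdict(self)
        d["pool_after"] = sorted(self.pool_after)
        return json.dumps(d, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**{**d, "input_shape": tuple(d.get("input_shape", (3, 224, 224)))})


@dataclass
class ParameterAccount:
    per_component: list[tuple[str, int]]
    total: int

    def __post_init__(self):
        assert self.total == sum(n for _, n in self.per_component)


class ClassifierNet(Module):
    """The instantiated network.  ``forward`` returns logits; use
    ``predict_proba`` for softmax probabilities."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        in_ch = spec.input_shape[0]
        self.blocks: list[ConvBlock] = []
        for i, f in enumerate(spec.block_filters, start=1):
            block = ConvBlock(ConvBlockSpec(in_ch, f, l2_lambda=spec.l2_lambda), rng)
            setattr(self, f"block{i}", block)
            self.blocks.append(block)
            in_ch = f
        self.attention = None
        if spec.attention_after_final_pool:
            self.attention = HybridAttention(
                AttentionSpec(in_ch, spec.attention_ratio), rng
            )
        self.dense = Dense(in_ch, spec.head_width, rng)
        self.classifier = Dense(spec.head_width, spec.num_classes, rng)

    def forward(self, x, *, training=False, rng=None):
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(x)
        expected = self.spec.input_shape[0]
        if x.data.shape[1] != expected:
            raise ValueError(
                f"model expects {expected} input channels, received {x.data.shape[1]}"
            )
        h = x
        for i, block in enumerate(self.blocks, start=1):
            h = block(h, training=training)
            if i in self.spec.pool_after:
                h = ad.maxpool2x2(h)
        if self.attention is not None:
            h = self.attention(h, training=training)
        h = ad.mean(h, axis=(2, 3))                      # global average pooling
        h = ad.relu(self.dense(h, training=training))
        if training and self.spec.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward with dropout requires an rng")
            h = ad.dropout(h, self.spec.dropout_rate, rng)
        return self.classifier(h, training=training)

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        """Class probabilities for an (N, C, H, W) array, in inference mode."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        with ad.no_grad():
            for start in range(0, len(x), batch_size):
                logits = self.forward(ad.Tensor(x[start:start + batch_size]))
                out.append(softmax(logits.data.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, x, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def output_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Per-stage output shapes for a single input image."""
        _, h, w = self.spec.input_shape
        rows = []
        for i, f in enumerate(self.spec.block_filters, start=1):
            rows.append((f"block{i}", (f, h, w)))
            if i in self.spec.pool_after:
                h, w = h // 2, w // 2
                rows.append((f"maxpool{i}", (f, h, w)))
        c = self.spec.block_filters[-1]
        if self.attention is not None:
            rows.append(("hybrid_attention", (c, h, w)))
        rows.append(("global_avg_pool", (c,)))
        rows.append(("dense", (self.spec.head_width,)))
        rows.append(("classifier", (self.spec.num_classes,)))
        return rows


def build_model(spec: ArchitectureSpec, seed: int | np.random.Generator = 0) -> ClassifierNet:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ClassifierNet(spec, rng)


def _module_total(module: Module) -> int:
    return module.num_parameters()


def count_parameters(spec: ArchitectureSpec) -> ParameterAccount:
    """Enumerate every parameter tensor (including BN running statistics) of
    an instantiated model, grouped per component."""
    model = build_model(spec, np.random.default_rng(0))
    per_component: list[tuple[str, int]] = []
    for i, block in enumerate(model.blocks, start=1):
        per_component.append((f"block{i}", _module_total(block)))
    if model.attention is not None:
        per_component.append(("hybrid_attention", _module_total(model.attention)))
    per_component.append(("dense", _module_total(model.dense)))
    per_component.append(("classifier", _module_total(model.classifier)))
    total = sum(n for _, n in per_component)
    assert total == model.num_parameters()
    return ParameterAccount(per_component=per_component, total=total)


def model_summary(spec: ArchitectureSpec) -> str:
    """Human-readable per-layer listing; the final line carries the total."""
    model = build_model(spec, np.random.default_rng(0))
    account = count_parameters(spec)
    counts = dict(account.per_component)
    lines = [
        f"{'layer':<20}{'output shape':<20}{'params':>12}",
        "-" * 52,
    ]
    for name, shape in model.output_shapes():
        n = counts.get(name, 0)
        if name.startswith("maxpool") or name == "global_avg_pool":
            n = 0
        lines.append(f"{name:<20}{str(shape):<20}{n:>12,}")
    lines.append("-" * 52)
    lines.append(f"{'total':<20}{'':<20}{account.total:>12,}")
    return "\n".join(lines)
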