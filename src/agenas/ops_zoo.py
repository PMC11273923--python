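"""Candidate operators and building blocks for both search spaces.

Two families live here:

* the 11-operator registry used by the differentiable cell search
  (standard / separable / grouped / asymmetric-grouped convolutions,
  pooling, identity and the zero operator), and
* the inverted-residual (MBConv) and parallel-asymmetric-convolution
  blocks that populate the one-shot supernet's 16 choice layers.

All cell operators are channel-preserving at stride 1; blocks carry a
residual connection exactly when stride is 1 and input and output widths
match.  The parallel-asymmetric block splits its expanded channels into
two equal halves, convolved depthwise with 1x7 and 7x1 kernels
respectively, so the depthwise stage costs 7 taps per expanded channel —
cheaper than the k=3 (9-tap) and k=5 (25-tap) depthwise stages it
competes with, at identical block depth (3 weighted stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np

from . import nn


class OpKind(str, Enum):
    standard_conv = "standard_conv"
    separable_conv = "separable_conv"
    group_conv = "group_conv"
    asym_group_conv = "asym_group_conv"
    max_pool = "max_pool"
    avg_pool = "avg_pool"
    identity = "identity"
    zero = "zero"


@dataclass(frozen=True)
class OperatorSpec:
    """A candidate cell operator (declarative)."""

    name: str
    kernel: tuple[int, int]
    groups: int
    kind: OpKind
    stride: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = self.kind.value
        d["kernel"] = list(self.kernel)
        return d

    @staticmethod
    def from_dict(d: dict) -> "OperatorSpec":
        return OperatorSpec(name=d["name"], kernel=tuple(d["kernel"]),
                            groups=d["groups"], kind=OpKind(d["kind"]),
                            stride=d.get("stride", 1))


#: The differentiable-search operator registry, in its canonical order.
#: Group convolutions (groups=9) are each followed by a pointwise conv;
#: separable convolutions are applied twice; the asymmetric entries are
#: two-stage (1xk then kx1) grouped convolutions.
_SEARCH_OPERATORS: tuple[OperatorSpec, ...] = (
    OperatorSpec("conv_3x3", (3, 3), 1, OpKind.standard_conv),
    OperatorSpec("sep_conv_3x3", (3, 3), 1, OpKind.separable_conv),
    OperatorSpec("sep_conv_5x5", (5, 5), 1, OpKind.separable_conv),
    OperatorSpec("group_conv_3x3_g9", (3, 3), 9, OpKind.group_conv),
    OperatorSpec("group_conv_5x5_g9", (5, 5), 9, OpKind.group_conv),
    OperatorSpec("asym_conv_1x3_3x1_g9", (3, 3), 9, OpKind.asym_group_conv),
    OperatorSpec("asym_conv_1x7_7x1_g9", (7, 7), 9, OpKind.asym_group_conv),
    OperatorSpec("max_pool_3x3", (3, 3), 1, OpKind.max_pool),
    OperatorSpec("avg_pool_3x3", (3, 3), 1, OpKind.avg_pool),
    OperatorSpec("identity", (1, 1), 1, OpKind.identity),
    OperatorSpec("zero", (1, 1), 1, OpKind.zero),
)


def list_search_operators() -> tuple[OperatorSpec, ...]:
    """The 11 candidate operators of the cell search space, in order."""
    return _SEARCH_OPERATORS


def operator_by_name(name: str) -> OperatorSpec:
    for spec in _SEARCH_OPERATORS:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown operator {name!r}")


@dataclass(frozen=True)
class BlockSpec:
    """An inverted-residual or parallel-asymmetric supernet block.

    ``expand`` is the channel expansion ratio applied by the leading 1x1
    convolution; ``kernel`` is the depthwise kernel for ``mbconv`` (the
    parallel-asymmetric block always taps 7 cells per expanded channel).
    The expand convolution is kept even when ``expand == 1`` so that every
    block has exactly 3 weighted stages.
    """

    kind: str  # "mbconv" | "parallel_asym"
    cin: int
    cout: int
    stride: int = 1
    expand: float = 6.0
    kernel: int = 3
    use_se: bool = False
    se_reduction: int = 4

    def __post_init__(self):
        if self.kind not in ("mbconv", "parallel_asym"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kind == "mbconv" and self.kernel not in (3, 5):
            raise ValueError("mbconv kernel must be 3 or 5")
        e = self.expand * self.cin
        if abs(e - round(e)) > 1e-9:
            raise ValueError("expand * cin must be integral")
        if self.kind == "parallel_asym" and round(e) % 2:
            raise ValueError("parallel_asym needs an even expanded width")

    @property
    def expanded(self) -> int:
        return int(round(self.expand * self.cin))

    @property
    def has_residual(self) -> bool:
        return self.stride == 1 and self.cin == self.cout

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "BlockSpec":
        return BlockSpec(**d)


@dataclass(frozen=True)
class SEConfig:
    channels: int
    reduction: int = 4

    def __post_init__(self):
        if self.channels < self.reduction:
            raise ValueError("channels / reduction must be >= 1")

    @property
    def hidden(self) -> int:
        return max(self.channels // self.reduction, 1)


# ---------------------------------------------------------------------------
# runtime constructors (NumPy modules)
# ---------------------------------------------------------------------------

class _ReluConvBN(nn.Module):
    def __init__(self, channels, kernel, stride, groups, rng):
        self.conv = nn.Conv2d(channels, channels, kernel, stride, groups, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.conv(x.relu6()))


class _SepConv(nn.Module):
    """Depthwise + pointwise, applied twice (stride only in the first)."""

    def __init__(self, channels, kernel, stride, rng):
        self.stages = []
        for i, s in enumerate((stride, 1)):
            self.stages.append(nn.Sequential(
                nn.Conv2d(channels, channels, kernel, s, groups=channels, rng=rng),
                nn.Conv2d(channels, channels, 1, 1, rng=rng),
                nn.BatchNorm2d(channels),
            ))

    def forward(self, x):
        for stage in self.stages:
            x = stage(x.relu6())
        return x


class _GroupConv(nn.Module):
    """Grouped conv followed by a pointwise conv (separable-style)."""

    def __init__(self, channels, kernel, stride, groups, rng):
        self.gconv = nn.Conv2d(channels, channels, kernel, stride, groups, rng=rng)
        self.pconv = nn.Conv2d(channels, channels, 1, 1, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.pconv(self.gconv(x.relu6())))


class _AsymGroupConv(nn.Module):
    """Two-stage 1xk then kx1 grouped conv, then a pointwise conv."""

    def __init__(self, channels, k, stride, groups, rng):
        # the 1xk stage runs at full resolution; the kx1 stage strides
        self.conv_a = nn.Conv2d(channels, channels, (1, k), 1, groups, rng=rng)
        self.conv_b = nn.Conv2d(channels, channels, (k, 1), stride, groups, rng=rng)
        self.pconv = nn.Conv2d(channels, channels, 1, 1, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.pconv(self.conv_b(self.conv_a(x.relu6()))))


class _PoolBN(nn.Module):
    def __init__(self, channels, kind, stride):
        pool = nn.MaxPool2d if kind == "max" else nn.AvgPool2d
        self.pool = pool(3, stride)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.pool(x))


class _StridedIdentity(nn.Module):
    """Identity at stride > 1: a strided 1x1 conv + norm (reduction cells)."""

    def __init__(self, channels, stride, rng):
        self.conv = nn.Conv2d(channels, channels, 1, stride, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.conv(x))


def make_operator(spec: OperatorSpec, channels: int, stride: int = 1,
                  rng: np.random.Generator | None = None) -> nn.Module:
    """Instantiate a cell operator as a channel-preserving module."""
    if channels % spec.groups:
        raise ValueError(
            f"channels={channels} not divisible by groups={spec.groups} "
            f"for operator {spec.name!r}")
    rng = rng or np.random.default_rng(0)
    k = spec.kernel[0]
    if spec.kind is OpKind.standard_conv:
        return _ReluConvBN(channels, k, stride, 1, rng)
    if spec.kind is OpKind.separable_conv:
        return _SepConv(channels, k, stride, rng)
    if spec.kind is OpKind.group_conv:
        return _GroupConv(channels, k, stride, spec.groups, rng)
    if spec.kind is OpKind.asym_group_conv:
        return _AsymGroupConv(channels, k, stride, spec.groups, rng)
    if spec.kind is OpKind.max_pool:
        return _PoolBN(channels, "max", stride)
    if spec.kind is OpKind.avg_pool:
        return _PoolBN(channels, "avg", stride)
    if spec.kind is OpKind.identity:
        if stride == 1:
            return nn.Identity()
        return _StridedIdentity(channels, stride, rng)
    if spec.kind is OpKind.zero:
        return nn.Zero(stride)
    raise ValueError(f"unhandled operator kind {spec.kind}")


class MBConvBlock(nn.Module):
    """Inverted residual: expand 1x1 -> depthwise kxk -> project 1x1.

    Batch norm + ReLU6 after expand and depthwise stages, linear
    projection; the squeeze-excitation gate (optional) sits between the
    depthwise stage and the projection.
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        if spec.kind != "mbconv":
            raise ValueError("spec.kind must be 'mbconv'")
        rng = rng or np.random.default_rng(0)
        e = spec.expanded
        self.spec = spec
        self.expand_conv = nn.Conv2d(spec.cin, e, 1, 1, rng=rng)
        self.expand_bn = nn.BatchNorm2d(e)
        self.dw_conv = nn.Conv2d(e, e, spec.kernel, spec.stride, groups=e, rng=rng)
        self.dw_bn = nn.BatchNorm2d(e)
        self.se = (nn.SqueezeExcite(e, spec.se_reduction, rng=rng)
                   if spec.use_se else None)
        self.project_conv = nn.Conv2d(e, spec.cout, 1, 1, rng=rng)
        self.project_bn = nn.BatchNorm2d(spec.cout)

    def forward(self, x):
        h = self.expand_bn(self.expand_conv(x)).relu6()
        h = self.dw_bn(self.dw_conv(h)).relu6()
        if self.se is not None:
            h = self.se(h)
        h = self.project_bn(self.project_conv(h))
        if self.spec.has_residual:
            h = h + x
        return h


class ParallelAsymBlock(nn.Module):
    """Expand 1x1 -> split halves -> depthwise 1x7 / 7x1 -> concat -> project.

    The two halves see complementary channels; the stride is applied in
    the depthwise stage.  Three weighted stages, same depth as MBConv.
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        if spec.kind != "parallel_asym":
            raise ValueError("spec.kind must be 'parallel_asym'")
        rng = rng or np.random.default_rng(0)
        e = spec.expanded
        half = e // 2
        self.spec = spec
        self.half = half
        self.expand_conv = nn.Conv2d(spec.cin, e, 1, 1, rng=rng)
        self.expand_bn = nn.BatchNorm2d(e)
        # both branches downsample both dims when stride = 2
        self.dw_a = nn.Conv2d(half, half, (1, 7), spec.stride, groups=half, rng=rng)
        self.dw_b = nn.Conv2d(half, half, (7, 1), spec.stride, groups=half, rng=rng)
        self.dw_bn = nn.BatchNorm2d(e)
        self.se = (nn.SqueezeExcite(e, spec.se_reduction, rng=rng)
                   if spec.use_se else None)
        self.project_conv = nn.Conv2d(e, spec.cout, 1, 1, rng=rng)
        self.project_bn = nn.BatchNorm2d(spec.cout)

    def forward(self, x):
        h = self.expand_bn(self.expand_conv(x)).relu6()
        ha = self.dw_a(h[:, :self.half])
        hb = self.dw_b(h[:, self.half:])
        h = self.dw_bn(nn.concat([ha, hb], axis=1)).relu6()
        if self.se is not None:
            h = self.se(h)
        h = self.project_bn(self.project_conv(h))
        if self.spec.has_residual:
            h = h + x
        return h


def make_mbconv_block(spec: BlockSpec,
                      rng: np.random.Generator | None = None) -> MBConvBlock:
    return MBConvBlock(spec, rng=rng)


def make_parallel_asym_block(spec: BlockSpec,
                             rng: np.random.Generator | None = None) -> ParallelAsymBlock:
    return ParallelAsymBlock(spec, rng=rng)


def make_block(spec: BlockSpec, rng: np.random.Generator | None = None) -> nn.Module:
    if spec.kind == "mbconv":
        return make_mbconv_block(spec, rng=rng)
    return make_parallel_asym_block(spec, rng=rng)


def make_se_module(cfg: SEConfig,
                   rng: np.random.Generator | None = None) -> nn.SqueezeExcite:
    return nn.SqueezeExcite(cfg.channels, cfg.reduction, rng=rng)


def block_depth(spec: BlockSpec) -> int:
    """Weighted stages of a block; parallel branches count once."""
    return 3
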