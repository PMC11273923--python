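"""Analytic complexity accounting: multiply-accumulates, parameters, depth.

Counting conventions
--------------------
* One multiply-accumulate (MAC) is one FLOP; reported "GFLOPs" are
  MACs / 1e9.  Convolution and fully connected layers are counted;
  normalization, activations, pooling and element-wise adds are not.
* Grouped and depthwise convolutions divide MACs and weights by the
  group count.  Convolutions are bias-free; normalization contributes
  2 affine parameters per channel to the parameter count (and no MACs).
* Depth counts weighted *stages*: parallel branches within a block count
  once, so every supernet block contributes 3 regardless of kind; a
  squeeze-excitation gate is not a stage; and a pre-classifier pointwise
  convolution, global pooling and the final fully connected layer form a
  single classification stage.  A 16-block supernet network is therefore
  1 (stem) + 16 x 3 + 1 (classifier) = 50 stages deep.
* "same" padding everywhere: a stride-s layer maps n -> ceil(n / s).

The closed forms for a single inverted-residual block and its
parallel-asymmetric counterpart,

    F_m  = EXP2 * (Cin^2 + Cin*Cout + Cin*k^2) * h * w
    F_m' = EXP2 * (Cin^2 + Cin*Cout + Cin*7)   * h * w

count exactly the three convolution stages of a stride-1 block (expand,
depthwise, project) at output resolution h x w; their ratio
(Cin+Cout+7)/(Cin+Cout+k^2) is < 1 for k in {3, 5}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .ops_zoo import BlockSpec

__all__ = [
    "ComplexityReport",
    "BlockCostQuery",
    "mbconv_flops_closed_form",
    "parallel_asym_flops_closed_form",
    "parallel_asym_flops_ratio",
    "lower_arch",
    "count_network",
    "count_depth",
]


@dataclass(frozen=True)
class ComplexityReport:
    flops: int   # multiply-accumulates, exact
    params: int  # learnable scalars, exact
    depth: int   # weighted stages

    @property
    def flops_g(self) -> float:
        return self.flops / 1e9

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    def to_dict(self, units: str = "raw") -> dict:
        if units == "raw":
            return {"flops": self.flops, "params": self.params, "depth": self.depth}
        if units == "G":
            return {"flops_g": self.flops_g, "params_m": self.params_m,
                    "depth": self.depth}
        if units == "M":
            return {"flops_m": self.flops / 1e6, "params_m": self.params_m,
                    "depth": self.depth}
        raise ValueError(f"unknown units {units!r}")


@dataclass(frozen=True)
class BlockCostQuery:
    """Inputs of the closed-form block costs (output resolution h x w)."""

    cin: int
    cout: int
    k: int = 3
    exp: float = 6.0
    h: int = 1
    w: int = 1

    def __post_init__(self):
        if min(self.cin, self.cout, self.k, self.h, self.w) < 1 or self.exp <= 0:
            raise ValueError("all BlockCostQuery fields must be positive")

    @property
    def expanded(self) -> int:
        e = self.exp * self.cin
        if abs(e - round(e)) > 1e-9:
            raise ValueError("exp * cin must be integral")
        return int(round(e))


def mbconv_flops_closed_form(q: BlockCostQuery) -> int:
    """EXP2 * (Cin^2 + Cin*Cout + Cin*k^2) * h * w, as an exact integer."""
    e = q.expanded
    return (e * q.cin + e * q.cout + e * q.k * q.k) * q.h * q.w


def parallel_asym_flops_closed_form(q: BlockCostQuery) -> int:
    """EXP2 * (Cin^2 + Cin*Cout + Cin*7) * h * w (k is ignored)."""
    e = q.expanded
    return (e * q.cin + e * q.cout + e * 7) * q.h * q.w


def parallel_asym_flops_ratio(cin: int, cout: int, k: int) -> Fraction:
    """Cost ratio parallel-asym / mbconv: (Cin+Cout+7)/(Cin+Cout+k^2)."""
    return Fraction(cin + cout + 7, cin + cout + k * k)


# ---------------------------------------------------------------------------
# architecture lowering
# ---------------------------------------------------------------------------

def _ceil_div(n: int, s: int) -> int:
    return math.ceil(n / s)


def _block_layers(spec: BlockSpec, h: int, w: int) -> tuple[list[dict], int, int]:
    """Lower one supernet block to primitive conv layers at resolution h x w."""
    e = spec.expanded
    ho, wo = _ceil_div(h, spec.stride), _ceil_div(w, spec.stride)
    layers = [
        {"op": "conv", "cin": spec.cin, "cout": e, "kh": 1, "kw": 1,
         "groups": 1, "h": h, "w": w, "bn": True, "stage": True},
    ]
    if spec.kind == "mbconv":
        layers.append({"op": "conv", "cin": e, "cout": e, "kh": spec.kernel,
                       "kw": spec.kernel, "groups": e, "h": ho, "w": wo,
                       "bn": True, "stage": True})
    else:
        half = e // 2
        layers.append({"op": "conv", "cin": half, "cout": half, "kh": 1,
                       "kw": 7, "groups": half, "h": ho, "w": wo,
                       "bn": False, "stage": True})
        layers.append({"op": "conv", "cin": half, "cout": half, "kh": 7,
                       "kw": 1, "groups": half, "h": ho, "w": wo,
                       "bn": False, "stage": False})  # parallel: same stage
        layers.append({"op": "bn", "channels": e})
    if spec.use_se:
        hidden = max(e // spec.se_reduction, 1)
        layers.append({"op": "fc", "cin": e, "cout": hidden, "bias": True,
                       "stage": False})
        layers.append({"op": "fc", "cin": hidden, "cout": e, "bias": True,
                       "stage": False})
    layers.append({"op": "conv", "cin": e, "cout": spec.cout, "kh": 1, "kw": 1,
                   "groups": 1, "h": ho, "w": wo, "bn": True, "stage": True})
    return layers, ho, wo


def lower_arch(arch: dict, input_hw: tuple[int, int]) -> list[dict]:
    """Flatten an architecture spec into primitive weighted layers.

    Accepts either the block-based form ``{stem, blocks, head, ...}`` or a
    pre-lowered ``{"layers": [...]}`` form in which each conv layer states
    an ``out_scale`` (total downsampling divisor at its output).
    """
    h, w = input_hw
    if "layers" in arch:
        out = []
        for lay in arch["layers"]:
            lay = dict(lay)
            if lay["op"] == "conv" and "h" not in lay:
                sc = lay.get("out_scale", 1)
                lay["h"], lay["w"] = _ceil_div(h, sc), _ceil_div(w, sc)
            out.append(lay)
        return out
    for key in ("stem", "blocks", "head", "num_classes"):
        if key not in arch:
            raise ValueError(f"architecture spec missing {key!r}")
    layers: list[dict] = []
    stem = arch["stem"]
    cin = arch.get("input_channels", 3)
    h, w = _ceil_div(h, stem["stride"]), _ceil_div(w, stem["stride"])
    layers.append({"op": "conv", "cin": cin, "cout": stem["cout"],
                   "kh": stem["kernel"], "kw": stem["kernel"], "groups": 1,
                   "h": h, "w": w, "bn": True, "stage": True})
    c = stem["cout"]
    for bd in arch["blocks"]:
        spec = bd if isinstance(bd, BlockSpec) else BlockSpec.from_dict(bd)
        if spec.cin != c:
            raise ValueError(
                f"block cin={spec.cin} does not chain from previous cout={c}")
        blayers, h, w = _block_layers(spec, h, w)
        layers.extend(blayers)
        c = spec.cout
    head = arch["head"]
    if head["type"] == "conv_gap_fc":
        # the pre-classifier pointwise conv, pooling and the fully
        # connected layer together form one classification stage
        layers.append({"op": "conv", "cin": c, "cout": head["cout"], "kh": 1,
                       "kw": 1, "groups": 1, "h": h, "w": w, "bn": True,
                       "stage": False})
        c = head["cout"]
    elif head["type"] != "gap_fc":
        raise ValueError(f"unknown head type {head['type']!r}")
    layers.append({"op": "fc", "cin": c, "cout": arch["num_classes"],
                   "bias": True, "stage": True})
    return layers


def _layer_cost(lay: dict) -> tuple[int, int]:
    """(MACs, params) of one primitive layer."""
    if lay["op"] == "conv":
        g = lay.get("groups", 1)
        wpc = (lay["cin"] // g) * lay["kh"] * lay["kw"]
        weights = lay["cout"] * wpc
        macs = weights * lay["h"] * lay["w"]
        params = weights + (2 * lay["cout"] if lay.get("bn", True) else 0)
        return macs, params
    if lay["op"] == "fc":
        weights = lay["cin"] * lay["cout"]
        params = weights + (lay["cout"] if lay.get("bias", True) else 0)
        return weights, params
    if lay["op"] == "bn":
        return 0, 2 * lay["channels"]
    raise ValueError(f"unknown primitive {lay['op']!r}")


def count_network(arch: dict, input_hw: int | tuple[int, int]) -> ComplexityReport:
    """Exact MAC / parameter / depth report for a declared network."""
    if isinstance(input_hw, int):
        input_hw = (input_hw, input_hw)
    layers = lower_arch(arch, input_hw)
    flops = params = depth = 0
    for lay in layers:
        f, p = _layer_cost(lay)
        flops += f
        params += p
        if lay["op"] in ("conv", "fc") and lay.get("stage", True):
            depth += 1
    return ComplexityReport(flops=flops, params=params, depth=depth)


def count_block(spec: BlockSpec, input_hw: int | tuple[int, int]) -> ComplexityReport:
    """Report for a single block at the given *input* resolution."""
    if isinstance(input_hw, int):
        input_hw = (input_hw, input_hw)
    layers, _, _ = _block_layers(spec, *input_hw)
    flops = params = depth = 0
    for lay in layers:
        f, p = _layer_cost(lay)
        flops += f
        params += p
        if lay["op"] in ("conv", "fc") and lay.get("stage", True):
            depth += 1
    return ComplexityReport(flops=flops, params=params, depth=depth)


def count_depth(arch: dict, input_hw: int | tuple[int, int] = 64) -> int:
    """Weighted-stage depth (stem + 3 per block + classifier stages)."""
    return count_network(arch, input_hw).depth
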