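"""Reference architecture specs and channel-rounding utilities."""

from __future__ import annotations

from .ops_zoo import BlockSpec

__all__ = ["round_channels", "mobilenet_v2_spec"]


def round_channels(c: float, divisor: int = 8) -> int:
    """Round a (width-scaled) channel count to a multiple of ``divisor``,
    never dropping more than 10% below the unrounded value."""
    new_c = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if new_c < 0.9 * c:
        new_c += divisor
    return new_c


# MobileNetV2 inverted-residual schedule: (expand, cout, repeats, stride)
_MBV2_SCHEDULE = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)


def mobilenet_v2_spec(width_mult: float = 1.0, num_classes: int = 76,
                      input_channels: int = 3, kernel: int = 3) -> dict:
    """Declarative MobileNetV2 with a distribution head of ``num_classes``.

    Every block keeps its expand convolution (3 weighted stages), including
    the first expand-ratio-1 block.
    """
    stem_c = round_channels(32 * width_mult)
    blocks: list[dict] = []
    cin = stem_c
    for t, c, n, s in _MBV2_SCHEDULE:
        cout = round_channels(c * width_mult)
        for i in range(n):
            blocks.append(BlockSpec(
                kind="mbconv", cin=cin, cout=cout,
                stride=s if i == 0 else 1, expand=float(t),
                kernel=kernel).to_dict())
            cin = cout
    head_c = round_channels(1280 * max(width_mult, 1.0))
    return {
        "name": f"mobilenet_v2_{width_mult:g}x",
        "input_channels": input_channels,
        "num_classes": num_classes,
        "stem": {"cout": stem_c, "kernel": 3, "stride": 2},
        "blocks": blocks,
        "head": {"type": "conv_gap_fc", "cout": head_c},
    }
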