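"""Trainable-parameter accounting for the six benchmark CNN architectures.

Each architecture is enumerated layer by layer following its standard
model-zoo definition (the ImageNet reference implementation), so parameter
totals are computed from first principles rather than quoted.  Counting
rules:

* convolution ``C_in x C_out x k x k`` (+ ``C_out`` if biased),
  divided by ``groups`` for grouped/depthwise convolutions;
* batch normalisation contributes ``2 * C`` (scale and shift);
* a linear layer contributes ``C_in * C_out + C_out``.

In the transfer-learning regime only the final classification layer is
replaced and updated, so the trainable count is that layer's parameter
count; trained from scratch every parameter is trainable.
"""

from __future__ import annotations

ARCHITECTURES = (
    "resnet18",
    "resnet50",
    "densenet121",
    "vgg16",
    "efficientnet_b0",
    "mobilenet_v3_small",
)


def _conv(c_in: int, c_out: int, k: int, *, groups: int = 1, bias: bool = False) -> int:
    return (c_in // groups) * c_out * k * k + (c_out if bias else 0)


def _bn(c: int) -> int:
    return 2 * c


def _linear(c_in: int, c_out: int) -> int:
    return c_in * c_out + c_out


# ---------------------------------------------------------------------------
# ResNet family


def _resnet_basic_block(c_in: int, c_out: int, downsample: bool) -> int:
    n = _conv(c_in, c_out, 3) + _bn(c_out) + _conv(c_out, c_out, 3) + _bn(c_out)
    if downsample:
        n += _conv(c_in, c_out, 1) + _bn(c_out)
    return n


def _resnet_bottleneck(c_in: int, width: int, downsample: bool) -> int:
    c_out = width * 4
    n = (
        _conv(c_in, width, 1)
        + _bn(width)
        + _conv(width, width, 3)
        + _bn(width)
        + _conv(width, c_out, 1)
        + _bn(c_out)
    )
    if downsample:
        n += _conv(c_in, c_out, 1) + _bn(c_out)
    return n


def _resnet(block_counts: tuple[int, ...], bottleneck: bool, n_classes: int) -> tuple[int, int]:
    """Return (backbone_params, head_params)."""
    n = _conv(3, 64, 7) + _bn(64)  # stem
    c_in = 64
    expansion = 4 if bottleneck else 1
    for stage, blocks in enumerate(block_counts):
        width = 64 * 2**stage
        c_out = width * expansion
        for b in range(blocks):
            downsample = b == 0 and (stage > 0 or expansion != 1)
            if bottleneck:
                n += _resnet_bottleneck(c_in, width, downsample)
            else:
                n += _resnet_basic_block(c_in, c_out, downsample)
            c_in = c_out
    return n, _linear(c_in, n_classes)


# ---------------------------------------------------------------------------
# DenseNet-121


def _densenet121(n_classes: int) -> tuple[int, int]:
    growth, init = 32, 64
    n = _conv(3, init, 7) + _bn(init)
    c = init
    block_layers = (6, 12, 24, 16)
    for i, layers in enumerate(block_layers):
        for _ in range(layers):
            # dense layer: BN - 1x1 conv (bottleneck 4k) - BN - 3x3 conv (k)
            n += _bn(c) + _conv(c, 4 * growth, 1) + _bn(4 * growth) + _conv(4 * growth, growth, 3)
            c += growth
        if i < len(block_layers) - 1:  # transition halves channels
            n += _bn(c) + _conv(c, c // 2, 1)
            c //= 2
    n += _bn(c)  # final norm
    return n, _linear(c, n_classes)


# ---------------------------------------------------------------------------
# VGG-16 (plain, biased convolutions, no batch norm)

_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M")


def _vgg16(n_classes: int) -> tuple[int, int]:
    n = 0
    c = 3
    for v in _VGG16_CFG:
        if v == "M":
            continue
        n += _conv(c, v, 3, bias=True)
        c = v
    n += _linear(512 * 7 * 7, 4096) + _linear(4096, 4096)
    return n, _linear(4096, n_classes)


# ---------------------------------------------------------------------------
# EfficientNet-B0

# (expand_ratio, kernel, in, out, repeats)
_EFFB0_STAGES = (
    (1, 3, 32, 16, 1),
    (6, 3, 16, 24, 2),
    (6, 5, 24, 40, 2),
    (6, 3, 40, 80, 3),
    (6, 5, 80, 112, 3),
    (6, 5, 112, 192, 4),
    (6, 3, 192, 320, 1),
)


def _mbconv(c_in: int, c_out: int, k: int, expand: int) -> int:
    c_mid = c_in * expand
    n = 0
    if expand != 1:
        n += _conv(c_in, c_mid, 1) + _bn(c_mid)
    n += _conv(c_mid, c_mid, k, groups=c_mid) + _bn(c_mid)
    # squeeze-excitation: squeeze width = c_in // 4, biased 1x1 convs
    c_sq = max(1, c_in // 4)
    n += _conv(c_mid, c_sq, 1, bias=True) + _conv(c_sq, c_mid, 1, bias=True)
    n += _conv(c_mid, c_out, 1) + _bn(c_out)
    return n


def _efficientnet_b0(n_classes: int) -> tuple[int, int]:
    n = _conv(3, 32, 3) + _bn(32)
    for expand, k, c_in, c_out, repeats in _EFFB0_STAGES:
        for r in range(repeats):
            n += _mbconv(c_in if r == 0 else c_out, c_out, k, expand)
    n += _conv(320, 1280, 1) + _bn(1280)
    return n, _linear(1280, n_classes)


# ---------------------------------------------------------------------------
# MobileNetV3-Small

# (kernel, expanded, out, use_se)
_MBV3_SMALL_STAGES = (
    (3, 16, 16, True),
    (3, 72, 24, False),
    (3, 88, 24, False),
    (5, 96, 40, True),
    (5, 240, 40, True),
    (5, 240, 40, True),
    (5, 120, 48, True),
    (5, 144, 48, True),
    (5, 288, 96, True),
    (5, 576, 96, True),
    (5, 576, 96, True),
)


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _mbv3_block(c_in: int, c_exp: int, c_out: int, k: int, use_se: bool) -> int:
    n = 0
    if c_exp != c_in:
        n += _conv(c_in, c_exp, 1) + _bn(c_exp)
    n += _conv(c_exp, c_exp, k, groups=c_exp) + _bn(c_exp)
    if use_se:
        c_sq = _make_divisible(c_exp // 4)
        n += _conv(c_exp, c_sq, 1, bias=True) + _conv(c_sq, c_exp, 1, bias=True)
    n += _conv(c_exp, c_out, 1) + _bn(c_out)
    return n


def _mobilenet_v3_small(n_classes: int) -> tuple[int, int]:
    n = _conv(3, 16, 3) + _bn(16)
    c_in = 16
    for k, c_exp, c_out, use_se in _MBV3_SMALL_STAGES:
        n += _mbv3_block(c_in, c_exp, c_out, k, use_se)
        c_in = c_out
    n += _conv(96, 576, 1) + _bn(576)
    # classifier: 576 -> 1024 hidden linear, then the class head
    n += _linear(576, 1024)
    return n, _linear(1024, n_classes)


_BUILDERS = {
    "resnet18": lambda nc: _resnet((2, 2, 2, 2), False, nc),
    "resnet50": lambda nc: _resnet((3, 4, 6, 3), True, nc),
    "densenet121": _densenet121,
    "vgg16": _vgg16,
    "efficientnet_b0": _efficientnet_b0,
    "mobilenet_v3_small": _mobilenet_v3_small,
}


def count_parameters(architecture: str, n_classes: int = 5) -> tuple[int, int]:
    """Total and final-classification-layer parameter counts.

    Returns ``(total, head)`` where ``head`` is the parameter count of the
    final class-mapping linear layer — the only layer updated in the
    transfer-learning regime.
    """
    if architecture not in _BUILDERS:
        raise ValueError(
            f"unknown architecture {architecture!r}; choose from {ARCHITECTURES}"
        )
    backbone, head = _BUILDERS[architecture](n_classes)
    return backbone + head, head
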