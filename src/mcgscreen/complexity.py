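"""Analytic model-complexity accounting for the classifier backbones.

Parameter counts and FLOPs are computed by a layer-by-layer audit over
declarative architecture tables rather than by instantiating a deep
learning framework: every convolution, batch-norm and linear layer of
MobileNetV3-Small and ResNet-18 is enumerated with its exact shapes, and

* parameters = sum of trainable scalars (conv kernels, biases, the two
  learnable batch-norm scalars per channel, linear weights),
* FLOPs = 2 x multiply-accumulates of all conv and linear layers at the
  given input resolution (the batch-norm and activation costs are not
  counted; this 2xMAC convention is stated in every report header),
* model size (MB) = 4 bytes x parameters / 1e6 (32-bit float weights).

With a 2-way classification head the audit yields 1,519,906 parameters
for MobileNetV3-Small and 11,177,538 for ResNet-18.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

__all__ = [
    "Conv2dSpec",
    "BatchNormSpec",
    "LinearSpec",
    "ArchitectureAudit",
    "ComplexityReport",
    "mobilenet_v3_small",
    "resnet18",
    "cnn1d_baseline",
    "count_parameters",
    "count_flops",
    "complexity_report",
]

FLOPS_CONVENTION = "FLOPs = 2 x MACs over conv and linear layers only"


@dataclass
class Conv2dSpec:
    in_ch: int
    out_ch: int
    kernel: int
    stride: int = 1
    padding: int = 0
    groups: int = 1
    bias: bool = False
    # spatial size of the *input* to this conv; 0 means "operates on 1x1"
    # (filled in during shape propagation)
    in_side: int = 0

    @property
    def parameters(self) -> int:
        weights = self.kernel * self.kernel * (self.in_ch // self.groups) * self.out_ch
        return weights + (self.out_ch if self.bias else 0)

    def out_side(self) -> int:
        return (self.in_side + 2 * self.padding - self.kernel) // self.stride + 1

    @property
    def macs(self) -> int:
        side = self.out_side()
        return (
            self.kernel
            * self.kernel
            * (self.in_ch // self.groups)
            * self.out_ch
            * side
            * side
        )


@dataclass
class BatchNormSpec:
    channels: int

    @property
    def parameters(self) -> int:
        return 2 * self.channels  # scale + shift; running stats are not trainable

    macs = 0


@dataclass
class LinearSpec:
    in_features: int
    out_features: int
    bias: bool = True

    @property
    def parameters(self) -> int:
        return self.in_features * self.out_features + (self.out_features if self.bias else 0)

    @property
    def macs(self) -> int:
        return self.in_features * self.out_features


@dataclass
class ArchitectureAudit:
    """A named, ordered list of counted layers; not trainable."""

    name: str
    layers: list = field(default_factory=list)
    input_side: int = 224

    @property
    def parameter_count(self) -> int:
        return sum(layer.parameters for layer in self.layers)

    @property
    def flops(self) -> int:
        return 2 * sum(getattr(layer, "macs", 0) for layer in self.layers)


@dataclass
class ComplexityReport:
    name: str
    parameter_count: int
    flops: int
    model_size_mb: float
    convention: str = FLOPS_CONVENTION


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class _Builder:
    """Tracks the running spatial side while appending layers."""

    def __init__(self, input_side: int):
        self.side = input_side
        self.layers: list = []

    def conv(self, in_ch, out_ch, k, stride=1, padding=0, groups=1, bias=False, pooled=False):
        side = 1 if pooled else self.side
        spec = Conv2dSpec(in_ch, out_ch, k, stride, padding, groups, bias, in_side=side)
        self.layers.append(spec)
        if not pooled:
            self.side = spec.out_side()
        return spec

    def bn(self, ch):
        self.layers.append(BatchNormSpec(ch))

    def linear(self, n_in, n_out, bias=True):
        self.layers.append(LinearSpec(n_in, n_out, bias))


def _squeeze_excite(b: _Builder, channels: int) -> None:
    squeeze = _make_divisible(channels // 4, 8)
    # both 1x1 convs act on the globally pooled 1x1 map
    b.conv(channels, squeeze, 1, bias=True, pooled=True)
    b.conv(squeeze, channels, 1, bias=True, pooled=True)


# (kernel, expanded channels, output channels, squeeze-excite, stride)
_MOBILENET_V3_SMALL_BNECKS = [
    (3, 16, 16, True, 2),
    (3, 72, 24, False, 2),
    (3, 88, 24, False, 1),
    (5, 96, 40, True, 2),
    (5, 240, 40, True, 1),
    (5, 240, 40, True, 1),
    (5, 120, 48, True, 1),
    (5, 144, 48, True, 1),
    (5, 288, 96, True, 2),
    (5, 576, 96, True, 1),
    (5, 576, 96, True, 1),
]


def mobilenet_v3_small(num_classes: int = 2, input_side: int = 224) -> ArchitectureAudit:
    """MobileNetV3-Small: inverted residual bottlenecks with depthwise
    separable convolutions, squeeze-and-excite attention and hard-swish
    activations, topped by a 1024-wide hidden classifier layer."""
    b = _Builder(input_side)
    b.conv(3, 16, 3, stride=2, padding=1)
    b.bn(16)
    in_ch = 16
    for kernel, expanded, out_ch, use_se, stride in _MOBILENET_V3_SMALL_BNECKS:
        if expanded != in_ch:
            b.conv(in_ch, expanded, 1)
            b.bn(expanded)
        b.conv(expanded, expanded, kernel, stride=stride, padding=(kernel - 1) // 2, groups=expanded)
        b.bn(expanded)
        if use_se:
            _squeeze_excite(b, expanded)
        b.conv(expanded, out_ch, 1)
        b.bn(out_ch)
        in_ch = out_ch
    last_conv = 6 * in_ch  # 576
    b.conv(in_ch, last_conv, 1)
    b.bn(last_conv)
    b.linear(last_conv, 1024)
    b.linear(1024, num_classes)
    return ArchitectureAudit("mobilenet_v3_small", b.layers, input_side)


def resnet18(num_classes: int = 2, input_side: int = 224) -> ArchitectureAudit:
    """Standard ResNet-18: 7x7 stem, four stages of two basic blocks,
    global average pooling and a linear head."""
    b = _Builder(input_side)
    b.conv(3, 64, 7, stride=2, padding=3)
    b.bn(64)
    b.side = (b.side + 2 * 1 - 3) // 2 + 1  # 3x3 max pool, stride 2, padding 1
    in_ch = 64
    for stage, out_ch in enumerate([64, 128, 256, 512]):
        for block in range(2):
            stride = 2 if (stage > 0 and block == 0) else 1
            if stride != 1 or in_ch != out_ch:
                b.conv(in_ch, out_ch, 1, stride=stride)  # downsample shortcut
                b.bn(out_ch)
                b.side = b.side * stride  # undo: shortcut does not advance the main path
            b.conv(in_ch, out_ch, 3, stride=stride, padding=1)
            b.bn(out_ch)
            b.conv(out_ch, out_ch, 3, stride=1, padding=1)
            b.bn(out_ch)
            in_ch = out_ch
    b.linear(512, num_classes)
    return ArchitectureAudit("resnet18", b.layers, input_side)


def cnn1d_baseline(num_classes: int = 2, input_length: int = 224) -> ArchitectureAudit:
    """The 1-D CNN baseline used for direct time-series classification:
    four strided conv blocks (16/32/64/128 channels), global average
    pooling, linear head.  Audited with the same 2xMAC convention by
    treating length-L sequences as Lx1 images."""
    b = _Builder(input_length)

    def conv1d(in_ch, out_ch, k, stride):
        spec = Conv2dSpec(in_ch, out_ch, k, stride, padding=(k - 1) // 2, in_side=b.side)
        # 1-D layer piggybacking on the 2-D spec: kernel and MACs scale
        # with the output length, not its square
        length_out = (b.side + 2 * spec.padding - k) // stride + 1
        spec.kernel_1d = True
        spec._macs_1d = k * in_ch * out_ch * length_out
        b.layers.append(spec)
        b.side = length_out

    conv1d(1, 16, 7, 2)
    conv1d(16, 32, 5, 2)
    conv1d(32, 64, 5, 2)
    conv1d(64, 128, 3, 2)
    b.linear(128, num_classes)
    audit = ArchitectureAudit("cnn1d", b.layers, input_length)
    return audit


def count_parameters(model) -> int:
    """Exact count of trainable scalars for an audit or a trainable model."""
    if isinstance(model, ArchitectureAudit):
        # 1-D audit layers carry square-kernel Conv2dSpec entries whose
        # parameter formula would square the kernel; correct for those
        total = 0
        for layer in model.layers:
            if isinstance(layer, Conv2dSpec) and getattr(layer, "kernel_1d", False):
                total += layer.kernel * (layer.in_ch // layer.groups) * layer.out_ch + (
                    layer.out_ch if layer.bias else 0
                )
            else:
                total += layer.parameters
        return total
    if hasattr(model, "parameters"):
        return int(sum(p.size for p in model.parameters()))
    raise InvalidParameterError(f"cannot count parameters of {type(model).__name__}")


def count_flops(model, input_side: int = 224) -> int:
    """FLOPs = 2 x MACs over conv/linear layers at the given input size."""
    if isinstance(model, ArchitectureAudit):
        macs = 0
        for layer in model.layers:
            if hasattr(layer, "_macs_1d"):
                macs += layer._macs_1d
            else:
                macs += getattr(layer, "macs", 0)
        return 2 * macs
    if hasattr(model, "count_macs"):
        return 2 * int(model.count_macs())
    raise InvalidParameterError(f"cannot count FLOPs of {type(model).__name__}")


def complexity_report(model, name: str | None = None) -> ComplexityReport:
    params = count_parameters(model)
    flops = count_flops(model)
    return ComplexityReport(
        name=name or getattr(model, "name", type(model).__name__),
        parameter_count=params,
        flops=flops,
        model_size_mb=4.0 * params / 1e6,
    )
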