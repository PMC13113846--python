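"""Parameter, FLOP and model-size accounting for the backbones.

Counts come from an analytic layer-by-layer audit of the architecture
tables (FLOPs = 2 x multiply-accumulates over conv and linear layers at
3x224x224; model size assumes 32-bit weights).
"""

from mcgscreen.complexity import complexity_report
from mcgscreen.model import build_classifier

for arch in ("mobilenet_v3_small", "resnet18", "cnn1d", "compact_cnn"):
    report = complexity_report(build_classifier(arch), name=arch)
    print(
        f"{arch:20s} {report.parameter_count/1e6:8.3f} M params  "
        f"{report.flops/1e9:7.3f} GFLOPs  {report.model_size_mb:6.2f} MB"
    )

small = complexity_report(build_classifier("mobilenet_v3_small"))
big = complexity_report(build_classifier("resnet18"))
print(
    f"\nMobileNetV3-Small vs ResNet-18: "
    f"{100*(1-small.parameter_count/big.parameter_count):.1f}% fewer parameters, "
    f"{100*(1-small.flops/big.flops):.1f}% fewer FLOPs"
)
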