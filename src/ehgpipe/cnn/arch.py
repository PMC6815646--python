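"""CNN architecture description and layer-shape arithmetic.

The reference network is an 11-layer AlexNet-style stack operating on
482x482 grayscale waveform images:

    Conv(27, s5)@96 + ReLU
    MaxPool(2, s3)
    Conv(2, s1)@256 + LRN + ReLU
    MaxPool(2, s2)
    Conv(3, s1)@384 + LRN + ReLU
    Conv(3, s1, pad)@384 + ReLU
    Conv(3, s1, pad)@256 + ReLU
    MaxPool(3, s2)
    FC 4096 + ReLU + dropout(0.5)
    FC 4096 + ReLU + dropout(0.5)
    FC 2 + softmax

With pad=1 on the two padded conv layers the spatial trace is
482 -> 92 -> 31 -> 30 -> 15 -> 13 -> 13 -> 13 -> 6, which is the
self-consistent reading of the published layer table (whose literal pad=2
would give 15 and 17 instead; the literal variant remains available via
``pad_literal=True``).

A ``scaled`` variant keeps the same layer sequence on a 128x128 input with
filter counts divided by 8 and 256-wide FC layers, sized to train in
minutes on one CPU. Its geometry needs pad=1 on the fifth conv layer too
(otherwise the 3x3 map collapses below the final 3x3 pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "conv_output_size",
    "pool_output_size",
    "ConvSpec",
    "PoolSpec",
    "FCSpec",
    "CNNArchitecture",
    "TrainConfig",
    "build_architecture",
    "default_train_config",
]


def conv_output_size(n: int, kernel: int, stride: int, pad: int = 0) -> int:
    """Spatial output size of a convolution: floor((n + 2*pad - kernel)/stride) + 1."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if n + 2 * pad < kernel:
        raise ValueError(
            f"kernel {kernel} larger than padded input {n} + 2*{pad}"
        )
    return (n + 2 * pad - kernel) // stride + 1


def pool_output_size(n: int, kernel: int, stride: int) -> int:
    """Spatial output size of a pooling layer: floor((n - kernel)/stride) + 1."""
    if kernel > n:
        raise ValueError(f"pool kernel {kernel} larger than input {n}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return (n - kernel) // stride + 1


@dataclass(frozen=True)
class ConvSpec:
    kernel: int
    stride: int
    pad: int
    num_output: int
    lrn: bool = False  # cross-channel LRN between conv and ReLU
    lrn_local_size: int = 5
    lrn_alpha: float = 0.0001
    lrn_beta: float = 0.75
    lrn_k: float = 1.0  # framework-default bias constant


@dataclass(frozen=True)
class PoolSpec:
    kernel: int
    stride: int


@dataclass(frozen=True)
class FCSpec:
    num_output: int
    relu: bool = True
    dropout_ratio: float = 0.0


LayerSpec = ConvSpec | PoolSpec | FCSpec


@dataclass
class CNNArchitecture:
    """Ordered layer stack plus the square input size it expects."""

    input_size: int
    layers: list[LayerSpec] = field(default_factory=list)
    name: str = ""

    def shape_trace(self) -> list[tuple[int, int]]:
        """(spatial size, channels) after each conv/pool layer."""
        size, ch = self.input_size, 1
        trace = []
        for layer in self.layers:
            if isinstance(layer, ConvSpec):
                size = conv_output_size(size, layer.kernel, layer.stride, layer.pad)
                ch = layer.num_output
                trace.append((size, ch))
            elif isinstance(layer, PoolSpec):
                size = pool_output_size(size, layer.kernel, layer.stride)
                trace.append((size, ch))
        return trace

    def flattened_size(self) -> int:
        size, ch = (
            self.shape_trace()[-1] if self.shape_trace() else (self.input_size, 1)
        )
        return size * size * ch

    def parameter_count(self) -> int:
        total = 0
        size, ch = self.input_size, 1
        for layer in self.layers:
            if isinstance(layer, ConvSpec):
                total += layer.num_output * (ch * layer.kernel**2 + 1)
                size = conv_output_size(size, layer.kernel, layer.stride, layer.pad)
                ch = layer.num_output
            elif isinstance(layer, PoolSpec):
                size = pool_output_size(size, layer.kernel, layer.stride)
            else:
                fan_in = size * size * ch if size else ch
                total += layer.num_output * (fan_in + 1)
                size, ch = 0, layer.num_output
        return total


@dataclass
class TrainConfig:
    """Optimizer and initialization hyperparameters.

    ``lr_drop_period`` is in epochs; the learning rate is multiplied by
    ``lr_drop_factor`` every period (the published "gamma" duplicates the
    drop factor and is treated as its alias). ``weight_init_std`` is either
    a numeric Gaussian std or ``"he"`` for fan-in-scaled initialization.
    ``epochs`` bounds training in epochs; ``max_iterations`` bounds it in
    mini-batches; training stops at whichever comes first.
    """

    learning_rate: float = 0.001
    weight_decay: float = 0.0005
    momentum: float = 0.9
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    max_iterations: int = 20000
    dropout_ratio: float = 0.5
    weight_init_std: float | str = 0.1
    bias_init: float = 0.1
    batch_size: int = 64
    epochs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "weight_decay", "lr_drop_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_ratio < 1):
            raise ValueError(f"dropout_ratio must be in [0, 1), got {self.dropout_ratio}")
        if not (0 < self.bias_init < 1):
            raise ValueError(f"bias_init must be a small value in (0, 1), got {self.bias_init}")


def build_architecture(variant: str = "paper", pad_literal: bool = False) -> CNNArchitecture:
    """Build the reference ('paper') or CPU-scale ('scaled') architecture.

    ``pad_literal=True`` uses pad=2 on the two padded 3x3 conv layers as the
    published table literally states, breaking the narrated shape trace.
    """
    if variant == "paper":
        pad67 = 2 if pad_literal else 1
        layers: list[LayerSpec] = [
            ConvSpec(27, 5, 0, 96),
            PoolSpec(2, 3),
            ConvSpec(2, 1, 0, 256, lrn=True),
            PoolSpec(2, 2),
            ConvSpec(3, 1, 0, 384, lrn=True),
            ConvSpec(3, 1, pad67, 384),
            ConvSpec(3, 1, pad67, 256),
            PoolSpec(3, 2),
            FCSpec(4096, relu=True, dropout_ratio=0.5),
            FCSpec(4096, relu=True, dropout_ratio=0.5),
            FCSpec(2, relu=False),
        ]
        return CNNArchitecture(input_size=482, layers=layers, name="paper")
    if variant == "scaled":
        layers = [
            ConvSpec(27, 5, 0, 12),
            PoolSpec(2, 3),
            ConvSpec(2, 1, 0, 32, lrn=True),
            PoolSpec(2, 2),
            ConvSpec(3, 1, 1, 48, lrn=True),  # pad=1: keep the 3x3 map alive
            ConvSpec(3, 1, 1, 48),
            ConvSpec(3, 1, 1, 32),
            PoolSpec(3, 2),
            FCSpec(256, relu=True, dropout_ratio=0.5),
            FCSpec(256, relu=True, dropout_ratio=0.5),
            FCSpec(2, relu=False),
        ]
        return CNNArchitecture(input_size=128, layers=layers, name="scaled")
    raise ValueError(f"unknown variant {variant!r}; expected 'paper' or 'scaled'")


def default_train_config(variant: str = "paper", **overrides) -> TrainConfig:
    """Variant-appropriate training defaults.

    The reference variant keeps the published Gaussian std=0.1 init and
    batch size 64. The scaled variant defaults to He initialization (std=0.1
    saturates the softmax at init for fan-ins of several hundred on [0,1]
    images) and batch size 16.
    """
    if variant == "paper":
        base = dict(weight_init_std=0.1, batch_size=64)
    elif variant == "scaled":
        base = dict(weight_init_std="he", batch_size=16)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    base.update(overrides)
    return TrainConfig(**base)
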