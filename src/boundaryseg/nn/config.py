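"""Network and training configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ConfigError

__all__ = ["NetworkConfig", "TrainingConfig", "HEAD_PLACEMENTS", "SUPERVISION_KINDS"]

HEAD_PLACEMENTS = ("encoder", "decoder", "both")
SUPERVISION_KINDS = ("sampled_points", "boundary_mask")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the boundary-supervised U-Net.

    ``depth`` encoder blocks (each two 3x3 convolutions + ReLU, followed
    by 2x max-pooling), a bottleneck block, and ``depth`` mirrored decoder
    blocks with skip concatenation.  A prediction head (1x1 convolution +
    direct nearest-neighbour upsampling to input resolution + sigmoid) is
    attached after each convolution block named by ``head_placement``, so
    the number of supervision stages is depth / depth / 2*depth for
    encoder / decoder / both.
    """

    depth: int = 4
    base_channels: int = 16
    head_placement: str = "both"
    supervision: str = "sampled_points"
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")
        if self.base_channels < 4:
            raise ConfigError("base_channels must be >= 4")
        if self.head_placement not in HEAD_PLACEMENTS:
            raise ConfigError(f"head_placement must be one of {HEAD_PLACEMENTS}")
        if self.supervision not in SUPERVISION_KINDS:
            raise ConfigError(f"supervision must be one of {SUPERVISION_KINDS}")
        h, w = self.input_size
        f = 2**self.depth
        if h % f or w % f:
            raise ConfigError(
                f"input_size {self.input_size} must be divisible by 2^depth = {f}"
            )

    @property
    def n_stages(self) -> int:
        return {"encoder": self.depth, "decoder": self.depth, "both": 2 * self.depth}[
            self.head_placement
        ]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation schedule (desk-scale defaults; full-scale values reachable).

    Full-scale reference values: learning rate 1e-4, 1200 epochs, batch 8,
    10-fold cross-validation.  Desk defaults keep a CPU smoke run in
    minutes.  The retained checkpoint is the one with the lowest
    validation total loss.
    """

    learning_rate: float = 1e-4
    max_epochs: int = 50
    batch_size: int = 4
    folds: int = 10
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
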