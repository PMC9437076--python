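"""Experiment configuration: loss-variant presets and hyperparameters.

Four objective variants share one network architecture and differ only
in which regularisers join the adversarial + cycle terms:

=============  ========  =======  =======
variant        l_cycle   l_ssim   l_flow
=============  ========  =======  =======
``cyclegan``   10        0        0
``structcgan`` 8         2        0
``flowcgan``   8         0        2
``sfcgan``     6         2        2
=============  ========  =======  =======
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StructuralError", "DegenerateInputError", "ConfigurationError",
           "LossWeights", "SSIMConstants", "FlowParams", "TrainConfig",
           "VARIANT_PRESETS", "VARIANTS", "load_config", "save_config"]


class StructuralError(ValueError):
    """Inputs violate a structural contract (shape/emptiness/finite-ness)."""


class DegenerateInputError(ValueError):
    """Inputs are structurally valid but degenerate (e.g. constant volume)."""


class ConfigurationError(ValueError):
    """Configuration values are inconsistent with the selected variant."""


VARIANT_PRESETS: dict[str, tuple[float, float, float]] = {
    "cyclegan": (10.0, 0.0, 0.0),
    "structcgan": (8.0, 2.0, 0.0),
    "flowcgan": (8.0, 0.0, 2.0),
    "sfcgan": (6.0, 2.0, 2.0),
}
VARIANTS = tuple(VARIANT_PRESETS)


@dataclass(frozen=True)
class LossWeights:
    """Generator-objective weights for one variant.

    A variant that omits a term must carry a zero weight for it; any
    other combination is rejected, so a weight/variant mismatch cannot
    silently change the objective.
    """

    variant: str = "sfcgan"
    lambda_cycle: float = 6.0
    lambda_ssim: float = 2.0
    lambda_flow: float = 2.0

    def __post_init__(self):
        if self.variant not in VARIANT_PRESETS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        _, s, f = VARIANT_PRESETS[self.variant]
        if s == 0.0 and self.lambda_ssim != 0.0:
            raise ConfigurationError(
                f"{self.variant} does not use the SSIM term; lambda_ssim "
                f"must be 0, got {self.lambda_ssim}")
        if f == 0.0 and self.lambda_flow != 0.0:
            raise ConfigurationError(
                f"{self.variant} does not use the flow term; lambda_flow "
                f"must be 0, got {self.lambda_flow}")

    @property
    def uses_ssim(self) -> bool:
        return self.lambda_ssim > 0.0

    @property
    def uses_flow(self) -> bool:
        return self.lambda_flow > 0.0

    @classmethod
    def for_variant(cls, variant: str) -> "LossWeights":
        if variant not in VARIANT_PRESETS:
            raise ConfigurationError(f"unknown variant {variant!r}")
        c, s, f = VARIANT_PRESETS[variant]
        return cls(variant=variant, lambda_cycle=c, lambda_ssim=s,
                   lambda_flow=f)


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilisers and window of the local structural-similarity index.

    The defaults (C1 = 1e-4, C2 = 9e-3 on [0, 1]-scaled images, uniform
    11 x 11 windows) are this model family's published choice; note C2
    differs from the conventional (0.03)^2 = 9e-4, which remains
    available by passing it explicitly.
    """

    c1: float = 0.0001
    c2: float = 0.009
    window: int = 11

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ConfigurationError("SSIM constants must be positive")
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError("SSIM window must be odd and positive")


@dataclass(frozen=True)
class FlowParams:
    """Farnebäck dense-flow hyperparameters (estimation-side defaults)."""

    pyr_levels: int = 3
    win_size: int = 15
    iterations: int = 3
    poly_n: int = 5
    poly_sigma: float = 1.1


@dataclass
class TrainConfig:
    """Optimisation schedule and scaled-architecture knobs.

    The published schedule is 200 epochs, batch 4, Adam at 2e-4 held
    for 100 epochs then decayed linearly to zero.  `ngf`/`ndf`/`n_res`
    scale the generator/discriminator width for desk-scale runs; the
    full-scale architecture is ngf = ndf = 64 with 9 residual blocks.
    """

    epochs: int = 200
    batch_size: int = 4
    lr: float = 0.0002
    lr_constant_epochs: int = 100
    lr_decay_epochs: int = 100
    buffer_capacity: int = 50
    variant: str = "sfcgan"
    seed: int = 0
    ngf: int = 64
    ndf: int = 64
    n_res: int = 9
    checkpoint_every: int = 0  # epochs; 0 = final checkpoint only
    ssim: SSIMConstants = field(default_factory=SSIMConstants)
    flow_params: FlowParams = field(default_factory=FlowParams)
    weights: LossWeights | None = None

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.buffer_capacity) <= 0:
            raise ConfigurationError("epochs/batch_size/buffer must be > 0")
        if self.lr <= 0:
            raise ConfigurationError("learning rate must be > 0")
        if self.lr_constant_epochs + self.lr_decay_epochs != self.epochs:
            raise ConfigurationError(
                "lr_constant_epochs + lr_decay_epochs must equal epochs")
        if self.weights is None:
            self.weights = LossWeights.for_variant(self.variant)
        elif self.weights.variant != self.variant:
            raise ConfigurationError("weights.variant disagrees with variant")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    return obj


def save_config(config: TrainConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config)))


def load_config(path: str | Path) -> TrainConfig:
    """Load a TrainConfig (with nested weights/SSIM blocks) from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    kwargs = dict(raw)
    if "ssim" in kwargs and isinstance(kwargs["ssim"], dict):
        kwargs["ssim"] = SSIMConstants(**kwargs["ssim"])
    if "flow_params" in kwargs and isinstance(kwargs["flow_params"], dict):
        kwargs["flow_params"] = FlowParams(**kwargs["flow_params"])
    if "weights" in kwargs and isinstance(kwargs["weights"], dict):
        kwargs["weights"] = LossWeights(**kwargs["weights"])
    try:
        return TrainConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
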