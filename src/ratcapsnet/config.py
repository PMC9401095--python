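"""Configuration records: architecture, augmentation, and run settings.

Everything round-trips through plain dicts so configs can be written to and
re-read from YAML/JSON untouched.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

VALID_HEAD_MODES = ("softmax", "sigmoid_binary")


class ConfigError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters for the classifier.

    ``base_width_n`` is the channel count produced by the first encoder stage
    from the 3-channel input; every later stage doubles it.  ``pfe_width_rho``
    is the per-branch channel count of the pyramid blocks; each pyramid output
    carries ``2 * pfe_width_rho`` channels.
    """

    base_width_n: int = 32
    pfe_width_rho: int = 16
    num_stages: int = 5
    pfe_stages: tuple[int, ...] = (2, 3, 4, 5)
    dense_sizes: tuple[int, int] = (512, 128)
    num_classes: int = 2
    input_hw: tuple[int, int] = (256, 256)
    leaky_slope: float = 0.1
    head_mode: str = "softmax"
    # kernel sizes of the three pyramid pair-fusion convolutions
    pfe_fusion_kernels: tuple[int, int, int] = (8, 9, 10)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pfe_stages", tuple(sorted(self.pfe_stages)))
        object.__setattr__(self, "dense_sizes", tuple(self.dense_sizes))
        object.__setattr__(self, "input_hw", tuple(self.input_hw))
        object.__setattr__(self, "pfe_fusion_kernels",
                           tuple(self.pfe_fusion_kernels))
        self.validate()

    def validate(self) -> None:
        if self.base_width_n < 1:
            raise ConfigError("base_width_n must be a positive integer")
        if self.pfe_width_rho < 1:
            raise ConfigError("pfe_width_rho must be a positive integer")
        if self.num_stages < 1:
            raise ConfigError("num_stages must be a positive integer")
        bad = [l for l in self.pfe_stages
               if not (2 <= l <= self.num_stages)]
        if bad:
            raise ConfigError(
                f"pfe_stages must be a subset of {{2..{self.num_stages}}}, "
                f"got {self.pfe_stages}")
        if len(self.dense_sizes) != 2 or min(self.dense_sizes) < 1:
            raise ConfigError("dense_sizes must be a pair of positive integers")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        div = 2 ** self.num_stages
        if len(self.input_hw) != 2 or min(self.input_hw) < div:
            raise ConfigError(f"input_hw must be a pair of dims >= {div}")
        if any(d % div for d in self.input_hw):
            raise ConfigError(
                f"input_hw dims must be divisible by 2^num_stages = {div}, "
                f"got {self.input_hw}")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ConfigError("leaky_slope must lie in (0, 1)")
        if self.head_mode not in VALID_HEAD_MODES:
            raise ConfigError(f"head_mode must be one of {VALID_HEAD_MODES}")
        if self.head_mode == "sigmoid_binary" and self.num_classes != 2:
            raise ConfigError("sigmoid_binary head requires num_classes == 2")
        if len(self.pfe_fusion_kernels) != 3 or min(self.pfe_fusion_kernels) < 1:
            raise ConfigError("pfe_fusion_kernels must be 3 positive kernels")

    def stage_channels(self, stage: int) -> int:
        """Output channel count of encoder stage ``stage`` (1-based)."""
        if not 1 <= stage <= self.num_stages:
            raise ConfigError(f"stage must be in 1..{self.num_stages}")
        return self.base_width_n * 2 ** (stage - 1)

    @property
    def head_input_size(self) -> int:
        return (self.stage_channels(self.num_stages)
                + len(self.pfe_stages) * 2 * self.pfe_width_rho)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pfe_stages"] = list(self.pfe_stages)
        d["dense_sizes"] = list(self.dense_sizes)
        d["input_hw"] = list(self.input_hw)
        d["pfe_fusion_kernels"] = list(self.pfe_fusion_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameter ranges for the stochastic augmentation operators."""

    rotation_degrees: tuple[float, float] = (-180.0, 180.0)
    flip_axes: tuple[str, ...] = ("horizontal", "vertical")
    shear_degrees: tuple[float, float] = (-15.0, 15.0)
    warp_strength: tuple[float, float] = (1.0, 4.0)
    erase_fraction: tuple[float, float] = (0.02, 0.10)
    noise_sigma: tuple[float, float] = (0.01, 0.05)
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_degrees", "shear_degrees", "warp_strength",
                     "erase_fraction", "noise_sigma", "blur_sigma"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(self, "flip_axes", tuple(self.flip_axes))
        self.validate()

    def validate(self) -> None:
        for name in ("rotation_degrees", "shear_degrees", "warp_strength",
                     "erase_fraction", "noise_sigma", "blur_sigma"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigError(f"{name} range is inverted: ({lo}, {hi})")
        for name in ("warp_strength", "erase_fraction", "noise_sigma",
                     "blur_sigma"):
            if getattr(self, name)[0] < 0:
                raise ConfigError(f"{name} must be non-negative")
        lo, hi = self.erase_fraction
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigError("erase_fraction must lie within [0, 0.5]")
        bad = set(self.flip_axes) - {"horizontal", "vertical"}
        if bad:
            raise ConfigError(f"unknown flip axes: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationConfig":
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one training run."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    data_root: str = ""
    split_ratio: float = 0.8
    balance_target: int = 3000
    loss: str = "auto"            # auto | cross_entropy | bce
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    output_dir: str = "runs/latest"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigError("split_ratio must lie in (0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.balance_target < 1:
            raise ConfigError("balance_target must be >= 1")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.loss not in ("auto", "cross_entropy", "bce"):
            raise ConfigError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "augmentation": self.augmentation.to_dict(),
            "data_root": self.data_root,
            "split_ratio": self.split_ratio,
            "balance_target": self.balance_target,
            "loss": self.loss,
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["network"] = NetworkConfig.from_dict(d.get("network", {}))
        d["augmentation"] = AugmentationConfig.from_dict(d.get("augmentation", {}))
        return cls(**d)

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
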