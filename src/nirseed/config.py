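"""Run configuration for the diffusion model and the seeding loop."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["DiffusionConfig", "SeedingConfig", "desk_config", "load_config", "save_config"]


@dataclass
class DiffusionConfig:
    """Hyperparameters of the unconditional diffusion model.

    Defaults are full-scale values (128x128, 1000 linear noise steps,
    batch 256, learning rate 1e-4); :func:`desk_config` returns a reduced
    configuration that trains in minutes on one CPU.
    """

    image_size: int = 128
    timesteps: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    variance_choice: str = "beta_tilde"  # "beta" or "beta_tilde"
    base_channels: int = 64
    channel_mult: tuple[int, ...] = (1, 1, 2, 2, 4)
    attention_resolutions: tuple[int, ...] = (32, 16, 8)
    time_embed_dim: int = 64
    groups: int = 8
    train_steps: int = 200_000
    batch_size: int = 256
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_mult = tuple(int(m) for m in self.channel_mult)
        self.attention_resolutions = tuple(int(r) for r in self.attention_resolutions)
        for name in (
            "image_size",
            "timesteps",
            "base_channels",
            "time_embed_dim",
            "groups",
            "train_steps",
            "batch_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.beta_start <= self.beta_end < 1.0):
            raise ValueError("need 0 < beta_start <= beta_end < 1")
        if self.variance_choice not in ("beta", "beta_tilde"):
            raise ValueError("variance_choice must be 'beta' or 'beta_tilde'")
        depth = len(self.channel_mult)
        if self.image_size % (2**depth):
            raise ValueError(
                f"image_size {self.image_size} must be a multiple of 2^depth = {2**depth}"
            )

    @property
    def depth(self) -> int:
        return len(self.channel_mult)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_mult"] = list(self.channel_mult)
        d["attention_resolutions"] = list(self.attention_resolutions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SeedingConfig:
    """Options for the iterative-seeding colorization loop."""

    translator: str = "highpass"  # identity | highpass | surrogate
    sigma: float = 2.3  # Gaussian filter std-dev, pixels
    seed: int = 0
    clip_output: bool = True
    surrogate_path: str | None = None

    def __post_init__(self) -> None:
        if self.translator not in ("identity", "highpass", "surrogate"):
            raise ValueError("translator must be identity, highpass or surrogate")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def desk_config(**overrides) -> DiffusionConfig:
    """A configuration small enough to train on one CPU in minutes.

    16x16 images, 200 noise steps, a 16-channel three-level U-Net with
    attention at 4x4 only.  beta_end scales with 1000/T so the terminal
    marginal stays near-isotropic (alpha_bar_T < 1e-4), matching the
    full-scale schedule's property.
    """
    base = dict(
        image_size=16,
        timesteps=200,
        beta_start=1e-4,
        beta_end=0.1,
        base_channels=16,
        channel_mult=(1, 2, 2),
        attention_resolutions=(4,),
        time_embed_dim=32,
        groups=8,
        train_steps=4000,
        batch_size=16,
        learning_rate=1e-3,
    )
    base.update(overrides)
    return DiffusionConfig(**base)


def load_config(path: str | Path) -> DiffusionConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DiffusionConfig.from_dict(data)


def save_config(config: DiffusionConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
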