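"""Run configuration: documented defaults plus YAML/key-value parsing."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Hyperparameters for training and tiled inference.

    Defaults follow the reference protocol: 64**3 blocks, adversarial
    weight ``alpha`` = 0.15, Adam learning rate 0.001, batch size 16.
    The inference stride defaults to half the patch size.
    """

    patch_size: int = 64
    stride: int = 32
    alpha: float = 0.15
    learning_rate: float = 0.001
    batch_size: int = 16
    steps: int = 300
    epochs: int = 1
    seed: int = 0
    n_classes: int = 3
    scales: int = 4
    base_channels: int = 16
    disc_channels: tuple = (16, 32, 64, 128)
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    standardize: bool = True
    data_dir: str = ""
    out_dir: str = ""

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if not (0 < self.stride <= self.patch_size):
            raise ValueError(
                f"stride must satisfy 0 < stride <= patch_size, got {self.stride} vs {self.patch_size}"
            )
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_classes != 3:
            raise ValueError("this package segments exactly 3 classes")
        if self.patch_size % (2 ** (self.scales - 1)) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2**(scales-1) = {2 ** (self.scales - 1)}"
            )
        self.disc_channels = tuple(int(c) for c in self.disc_channels)

    def to_dict(self) -> dict:
        return asdict(self)


_VALID_KEYS = {f.name for f in fields(RunConfig)}


def parse_config(source: str | Path | dict | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file, a mapping, or kwargs.

    Unknown keys raise a :class:`ValueError` listing the valid keys;
    invariant violations raise from the dataclass itself.
    """
    values: dict = {}
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {source} must contain a key-value mapping")
        values.update(loaded)
    elif isinstance(source, dict):
        values.update(source)
    elif source is not None:
        raise TypeError(f"unsupported config source: {type(source)!r}")
    values.update(overrides)

    unknown = set(values) - _VALID_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_VALID_KEYS)}"
        )
    return RunConfig(**values)
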