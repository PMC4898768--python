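"""Run configuration: one human-readable JSON file, validated on load.

The configuration captures every parameter that affects numeric output
(optics, noise, detection, statistics, seeds), round-trips exactly through
``save``/``load``, and hashes stably so result files can name the
configuration that produced them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

from . import io

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    # optics
    psf_sigma: float = 1.4
    image_shape: tuple[int, int] = (256, 256)
    bit_depth: int = 16
    # noise
    read_noise_sd: float = 10.0
    photon_scale: float = 1.0
    baseline_offset: float = 0.0
    # detection
    detection_alpha: float = 0.05
    candidate_k: float = 7.0
    fit_sigma: bool = False
    # statistics
    stats_alpha: float = 0.05
    welch: bool = False
    # experiment design
    conditions: tuple[str, ...] = ("control", "usmb")
    n_cells: int = 20
    n_experiments: int = 3

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if min(self.image_shape) < 32:
            raise ValueError("image dimensions must be >= 32")
        for name in ("detection_alpha", "stats_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.read_noise_sd < 0 or self.photon_scale < 0 or self.baseline_offset < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.candidate_k <= 0:
            raise ValueError("candidate_k must be > 0")
        if self.n_cells < 1 or self.n_experiments < 1:
            raise ValueError("n_cells and n_experiments must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition label is required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        data = dict(data)
        if "image_shape" in data:
            data["image_shape"] = tuple(data["image_shape"])
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def hash(self) -> str:
        return io.config_hash(self.to_dict())

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))


def save_config(config: RunConfig, path: str | Path) -> None:
    io.write_json(path, config.to_dict())


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(io.read_json(path))
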