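"""Study configuration: filtering thresholds, significance, clustering and
network settings, loaded from a single YAML/JSON file."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

TIME_FRAMES = ("TFH1", "TFH2", "TFD", "TFdelta")


class ConfigError(ValueError):
    """Raised for invalid study configuration."""


@dataclass
class ClusterSettings:
    """Two-tier clustering knobs (agglomerative + silhouette model selection)."""

    linkage: str = "average"
    max_k: int = 8
    min_silhouette: float = 0.5  # weak-structure floor (Rousseeuw): below it, keep one cluster
    silhouette_subsample: int = 2000

    def validate(self) -> None:
        if self.max_k < 2:
            raise ConfigError(f"max_k must be >= 2, got {self.max_k}")
        if not -1 <= self.min_silhouette <= 1:
            raise ConfigError("min_silhouette must be in [-1, 1]")
        if self.silhouette_subsample < 10:
            raise ConfigError("silhouette_subsample must be >= 10")


@dataclass
class NetworkSettings:
    """Which time frames get networks and the distance offset."""

    frames: tuple[str, ...] = ("TFD", "TFdelta")
    distance_offset: float = 0.0001

    def validate(self) -> None:
        for f in self.frames:
            if f not in TIME_FRAMES:
                raise ConfigError(f"unknown network frame {f!r}")
        if self.distance_offset <= 0:
            raise ConfigError("distance_offset must be positive")


@dataclass
class StudyConfig:
    """Full study configuration driving every pipeline stage.

    Defaults follow the analysis conventions: noise floor 1, drop series with
    more than 1/4 of timepoints missing, significance p = 0.01 with 100,000
    bootstrap resamples.
    """

    noise_floor: float = 1.0
    max_missing_fraction: float = 0.25
    p: float = 0.01
    n_boot: int = 100_000
    seed: int = 0
    reference_index: dict[str, int] = field(
        default_factory=lambda: {"TFH1": 0, "TFH2": 0, "TFD": 2, "TFdelta": 0}
    )
    time_units: dict[str, str] = field(
        default_factory=lambda: {"TFH1": "h", "TFH2": "h", "TFD": "d", "TFdelta": "h"}
    )
    log_transform: bool = False
    boxcox_omics: tuple[str, ...] = ("protein",)
    cluster: ClusterSettings = field(default_factory=ClusterSettings)
    network: NetworkSettings = field(default_factory=NetworkSettings)

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ConfigError(f"p must be in (0, 1), got {self.p}")
        if self.n_boot < 1000:
            raise ConfigError(f"n_boot must be >= 1000, got {self.n_boot}")
        if not 0 <= self.max_missing_fraction < 1:
            raise ConfigError(
                f"max_missing_fraction must be in [0, 1), got {self.max_missing_fraction}"
            )
        if self.noise_floor < 0:
            raise ConfigError("noise_floor must be non-negative")
        self.boxcox_omics = tuple(self.boxcox_omics)
        self.cluster.validate()
        self.network.validate()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["boxcox_omics"] = list(self.boxcox_omics)
        d["network"]["frames"] = list(self.network.frames)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        if "cluster" in d and isinstance(d["cluster"], dict):
            d["cluster"] = ClusterSettings(**d["cluster"])
        if "network" in d and isinstance(d["network"], dict):
            net = dict(d["network"])
            if "frames" in net:
                net["frames"] = tuple(net["frames"])
            d["network"] = NetworkSettings(**net)
        if "boxcox_omics" in d:
            d["boxcox_omics"] = tuple(d["boxcox_omics"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
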