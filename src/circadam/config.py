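"""Experiment configuration: YAML schema, validation and hashing.

A config names the DAM files, maps channels to genotypes, fixes the light
schedule and analysis windows, and records every statistical setting so the
choices the literature leaves unstated (periodogram bin width and range,
significance level, death rule) are always auditable from the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .schedule import LightSchedule

__all__ = ["ExperimentConfig", "DamFileSpec", "ConfigError"]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass
class DamFileSpec:
    path: str
    monitor: int = 1
    # channel (1-32) -> {"genotype": ..., "sex": ...}
    channels: dict[int, dict[str, str]] = field(default_factory=dict)


@dataclass
class ExperimentConfig:
    dam_files: list[DamFileSpec] = field(default_factory=list)
    n_ld_days: int = 5
    n_dd_days: int = 6
    lights_on: float = 8.0
    lights_off: float = 20.0
    temperature: float = 25.0
    profile_days: list[int] | None = None  # default: last 3 LD days
    dd_analysis_days: int = 6
    alpha: float = 0.05
    periodogram_bin_min: int = 10
    period_range_h: tuple[float, float] = (16.0, 32.0)
    periodogram_correction: str = "sidak-exact"
    death_run_hours: float = 24.0
    per_fly_indices: bool = True
    output_dir: str = "circadam_out"
    seed: int = 0

    # -- derived --------------------------------------------------------
    def schedule(self) -> LightSchedule:
        return LightSchedule.ld_dd(
            self.n_ld_days, self.n_dd_days,
            self.lights_on, self.lights_off, self.temperature,
        )

    def resolved_profile_days(self) -> list[int]:
        if self.profile_days is not None:
            return list(self.profile_days)
        return list(range(max(0, self.n_ld_days - 3), self.n_ld_days))

    def dd_window(self) -> tuple[int, int]:
        start = self.n_ld_days
        return (start, start + self.dd_analysis_days)

    # -- validation -----------------------------------------------------
    def validate(self, check_paths: bool = True) -> None:
        errors: list[str] = []
        if self.n_ld_days < 1:
            errors.append("n_ld_days must be >= 1")
        if self.n_dd_days < 0:
            errors.append("n_dd_days must be >= 0")
        if not 0 < self.alpha < 1:
            errors.append("alpha must lie in (0, 1)")
        if self.periodogram_bin_min < 1:
            errors.append("periodogram_bin_min must be >= 1")
        lo, hi = self.period_range_h
        if not 0 < lo < hi:
            errors.append("period_range_h must be an increasing positive pair")
        if self.death_run_hours <= 0:
            errors.append("death_run_hours must be > 0")
        if self.dd_analysis_days > self.n_dd_days:
            errors.append("dd_analysis_days exceeds recorded DD days")
        for d in self.resolved_profile_days():
            if not 0 <= d < self.n_ld_days:
                errors.append(f"profile day {d} outside the LD phase")
        if not self.dam_files:
            errors.append("no DAM files configured")
        for spec in self.dam_files:
            if check_paths and not Path(spec.path).exists():
                errors.append(f"DAM file not found: {spec.path}")
            for ch in spec.channels:
                if not 1 <= int(ch) <= 32:
                    errors.append(f"channel {ch} outside 1..32 in {spec.path}")
        if errors:
            raise ConfigError("; ".join(errors))

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["period_range_h"] = list(self.period_range_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        files = [
            DamFileSpec(
                path=f["path"],
                monitor=int(f.get("monitor", 1)),
                channels={int(k): dict(v) for k, v in f.get("channels", {}).items()},
            )
            for f in d.pop("dam_files", [])
        ]
        if "period_range_h" in d:
            d["period_range_h"] = tuple(d["period_range_h"])
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(dam_files=files, **known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable short hash of the analysis-relevant configuration.

        The output directory is excluded so the same analysis written to two
        locations produces identical report contents.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
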