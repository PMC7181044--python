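"""Pipeline configuration: schema-validated YAML/JSON, hashing, defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .frames import FrameSchedule, default_schedule

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown key, bad value, bad type)."""


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    ``k2ref`` is either the string "fitted" (per-animal SRTM estimate from
    the cortex, the default) or a fixed population value in 1/min.
    ``frame_durations_s`` of None means the packaged default 90-min
    schedule.
    """

    frame_durations_s: "tuple[float, ...] | None" = None
    window_duration_min: float = 30.0
    window_step_min: float = 10.0
    t_star_min: float = 40.0
    k2ref: "str | float" = "fitted"
    stats_engine: str = "anova_tukey"
    baseline_group: str = "2"
    analysis_window_min: tuple[float, float] = (40.0, 70.0)
    r2_threshold: float = 0.90
    excluded_regions: tuple[str, ...] = ("MB",)
    noise_scale: "float | None" = None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.k2ref, str):
            if self.k2ref != "fitted":
                raise ConfigError(
                    f"k2ref must be 'fitted' or a positive number, got {self.k2ref!r}"
                )
        elif not self.k2ref > 0:
            raise ConfigError(f"fixed k2ref must be positive, got {self.k2ref}")
        if self.stats_engine not in ("anova_tukey", "kruskal_dunn"):
            raise ConfigError(f"unknown stats engine {self.stats_engine!r}")
        if self.window_duration_min <= 0 or self.window_step_min <= 0:
            raise ConfigError("window duration and step must be positive")
        if not (0 < self.r2_threshold <= 1):
            raise ConfigError("r2_threshold must be in (0, 1]")
        a, b = self.analysis_window_min
        if not (0 <= a < b):
            raise ConfigError(f"bad analysis window [{a}, {b}]")

    @property
    def schedule(self) -> FrameSchedule:
        if self.frame_durations_s is None:
            return default_schedule()
        return FrameSchedule(tuple(self.frame_durations_s))

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {sorted(unknown)}; known keys: {sorted(known)}"
            )
        kwargs = dict(obj)
        for key in ("frame_durations_s", "excluded_regions", "analysis_window_min"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "baseline_group" in kwargs:
            kwargs["baseline_group"] = str(kwargs["baseline_group"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(obj)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_regions"] = list(d["excluded_regions"])
        d["analysis_window_min"] = list(d["analysis_window_min"])
        if d["frame_durations_s"] is not None:
            d["frame_durations_s"] = list(d["frame_durations_s"])
        return d

    def digest(self) -> str:
        """Short stable hash identifying the configuration in output files."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
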