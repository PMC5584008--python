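"""Pipeline configuration: defaults, validation, parsing and round-tripping.

Every printed constant of the method lives here, nowhere else:

- material attenuation ranges (lumen air -1000..-800, soft tissue -100..100,
  tagging 200..1400, interface artifact -800..600 HU)
- the -600 HU air cut and 200 HU tagging cut used for lumen detection
- spherical dilation radius 3 (the assumed partial-volume layer thickness)
- leaping distance 5 for layer classification
- Gaussian scales: 1 voxel for the directional second derivative and
  0.5 voxels for colonic-wall smoothing
- the 100 HU gate above which pseudo-enhanced soft tissue is rewritten
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .preprocess import ThresholdTable

__all__ = ["CleanseConfig", "ConfigError", "RunManifest", "parse_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration entries; message lists the keys."""


@dataclass
class CleanseConfig:
    """All tunables of the cleansing pipeline with the method's defaults."""

    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    dilation_radius: int = 3
    connectivity: int = 6
    leap_distance: int = 5
    slicewise: bool = True
    sigma_gdsd: float = 1.0
    gdsd_eps: float = 1e-4
    hu_window: tuple[float, float] = (-1000.0, 1400.0)
    sigma_wall: float = 0.5
    peh_hu_gate: float = 100.0
    sigma_omega: float = 1.0
    theta_mode: str = "apex_match"  # or "fixed"
    theta_fixed: float = 1.0
    projection_samples: int = 4096

    def __post_init__(self) -> None:
        errors = []
        for key in ("sigma_gdsd", "sigma_wall", "sigma_omega", "theta_fixed"):
            if getattr(self, key) <= 0:
                errors.append(key)
        for key in ("dilation_radius", "leap_distance", "projection_samples"):
            if int(getattr(self, key)) < 1:
                errors.append(key)
        if self.connectivity not in (6, 18, 26):
            errors.append("connectivity")
        if self.theta_mode not in ("apex_match", "fixed"):
            errors.append("theta_mode")
        lo, hi = self.hu_window
        if not hi > lo:
            errors.append("hu_window")
        if self.gdsd_eps <= 0:
            errors.append("gdsd_eps")
        if errors:
            raise ConfigError(f"invalid configuration values for: {', '.join(sorted(errors))}")
        self.hu_window = (float(lo), float(hi))


def _field_names(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def parse_config(path_or_mapping) -> CleanseConfig:
    """Build a :class:`CleanseConfig` from a YAML/JSON file or a mapping.

    Missing keys take the method defaults; unknown keys are rejected with a
    :class:`ConfigError` listing them.  ``thresholds`` may be a nested
    mapping of :class:`ThresholdTable` fields.
    """
    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must hold a mapping at top level")

    unknown = set(raw) - _field_names(CleanseConfig)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(sorted(unknown))}")

    kwargs = dict(raw)
    if "thresholds" in kwargs and isinstance(kwargs["thresholds"], dict):
        tdict = kwargs["thresholds"]
        bad = set(tdict) - _field_names(ThresholdTable)
        if bad:
            raise ConfigError(f"unknown threshold keys: {', '.join(sorted(bad))}")
        tkw = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in tdict.items()
        }
        try:
            kwargs["thresholds"] = ThresholdTable(**tkw)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    if "hu_window" in kwargs and isinstance(kwargs["hu_window"], (list, tuple)):
        kwargs["hu_window"] = tuple(kwargs["hu_window"])
    try:
        return CleanseConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    input_paths: list[str]
    software_version: str
    timings_s: dict[str, float]
    warnings: list[str]

    @classmethod
    def build(cls, cfg: CleanseConfig, input_paths: list[str], report) -> "RunManifest":
        from . import __version__

        return cls(
            config_hash=config_hash(cfg),
            input_paths=list(input_paths),
            software_version=__version__,
            timings_s=dict(report.timings_s),
            warnings=list(report.warnings),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg: CleanseConfig) -> str:
    """Stable hash of the effective configuration (identical configs hash equal)."""
    import hashlib

    blob = json.dumps(dump_config(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def dump_config(cfg: CleanseConfig, path: str | None = None) -> dict:
    """Serialise a config to a plain dict (and optionally a YAML file)."""
    d = dataclasses.asdict(cfg)
    d["thresholds"] = {
        k: list(v) if isinstance(v, tuple) else v for k, v in d["thresholds"].items()
    }
    d["hu_window"] = list(d["hu_window"])
    if path is not None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(d)), fh, sort_keys=True)
    return d
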