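"""Pipeline configuration with strict YAML round-tripping.

The default configuration reproduces the study constants: 25 dynamic
scans of 163 s each, the 1.8 fold-change threshold, the 0–4 Ki67 rubric
bins, and the five-genotype preset table. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .histo import KI67_RUBRIC
from .stats import DEFAULT_FOLD_THRESHOLD
from .synthetic import CurveParams, GenotypePreset, ScanSchedule, default_presets

__all__ = ["PipelineConfig"]


def _presets_to_dict(presets: list[GenotypePreset]) -> list[dict[str, Any]]:
    return [
        {
            "name": p.name,
            "between_placenta_sd": p.between_placenta_sd,
            **asdict(p.params),
        }
        for p in presets
    ]


def _presets_from_dict(raw: list[dict[str, Any]]) -> list[GenotypePreset]:
    presets = []
    for entry in raw:
        entry = dict(entry)
        name = entry.pop("name")
        sd = entry.pop("between_placenta_sd", 0.10)
        try:
            params = CurveParams(**entry)
        except TypeError as exc:
            raise ConfigError(f"preset {name!r}: {exc}") from exc
        presets.append(GenotypePreset(name=name, params=params, between_placenta_sd=sd))
    return presets


@dataclass
class PipelineConfig:
    seed: int = 0
    n_scans: int = 25
    scan_duration_s: float = 163.0
    n_per_group: int = 8
    presets: list[GenotypePreset] = field(default_factory=default_presets)
    fold_change_threshold: float = DEFAULT_FOLD_THRESHOLD
    intensity_threshold: float | str = "otsu"
    smooth_window: int = 3
    rubric: list[list[float]] = field(
        default_factory=lambda: [list(pair) for pair in KI67_RUBRIC]
    )
    out_dir: str = "placentaq_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.schedule  # validates n_scans / scan_duration
        if self.fold_change_threshold <= 1:
            raise ConfigError("fold_change_threshold must exceed 1")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd and >= 1")
        if isinstance(self.intensity_threshold, str) and self.intensity_threshold != "otsu":
            raise ConfigError(
                f"intensity_threshold must be 'otsu' or a number, got {self.intensity_threshold!r}"
            )
        edges = [e for e, _ in self.rubric]
        if edges != sorted(edges) or any(not 0 < e < 1 for e in edges):
            raise ConfigError("rubric bin edges must be ascending fractions in (0, 1)")

    @property
    def schedule(self) -> ScanSchedule:
        return ScanSchedule(n_scans=self.n_scans, scan_duration=self.scan_duration_s)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["presets"] = _presets_to_dict(self.presets)
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "presets" in raw:
            raw["presets"] = _presets_from_dict(raw["presets"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)
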