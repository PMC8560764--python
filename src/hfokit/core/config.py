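"""Pipeline configuration: every tunable of every stage, YAML round-trippable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "DetectorConfig",
    "ClassifierConfig",
    "StatsConfig",
    "PipelineConfig",
]


@dataclass
class DetectorConfig:
    """Hilbert-detector tunables.

    The skewness->threshold mapping is affine-clamped:
    ``clamp(base + gain * max(0, skew), floor, ceiling)`` in SD units of the
    normalized envelope.
    """

    filter_order: int = 1000
    smooth_window_ms: float = 40.0
    threshold_base: float = 3.0
    threshold_gain: float = 0.5
    threshold_floor: float = 3.0
    # ceiling 4.0: with whole-series normalization, event-rich channels push
    # skewness far past 2 and a higher cap collapses recall on true bursts
    threshold_ceiling: float = 4.0
    boundary_fraction: float = 0.5  # walk-out to this fraction of threshold
    merge_gap_ms: float = 10.0
    min_duration_broad_ms: float = 20.0
    min_duration_fast_ms: float = 10.0
    dedup_overlap: float = 0.5  # cross-montage/band interval-overlap fraction
    use_bipolar: bool = True


@dataclass
class ClassifierConfig:
    """Time-frequency review tunables."""

    n_cycles: float = 7.0
    freq_min_hz: float = 32.0
    freq_max_hz: float = 600.0
    n_freqs: int = 40
    contour_fraction: float = 0.5
    context_ms: float = 250.0
    spike_lowpass_hz: float = 30.0
    spike_amp_z: float = 4.0
    spike_slope_z: float = 4.0
    spike_window_ms: float = 50.0
    artifact_rate_cap: float = 0.05


@dataclass
class IcaConfig:
    """Component-based artifact attenuation tunables."""

    enabled: bool = True
    n_components: Optional[int] = None
    highband_hz: float = 80.0
    highband_fraction_threshold: float = 0.60
    kurtosis_threshold: float = 20.0
    max_iter: int = 500
    tol: float = 1e-4


@dataclass
class StatsConfig:
    n_bootstrap: int = 1000
    n_permutations: int = 2000
    ez_percentile: float = 95.0
    ci_level: float = 0.95


@dataclass
class PipelineConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ica: IcaConfig = field(default_factory=IcaConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulation: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sections = {}
        for name, sub_cls in (
            ("detector", DetectorConfig),
            ("classifier", ClassifierConfig),
            ("ica", IcaConfig),
            ("stats", StatsConfig),
        ):
            raw = data.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(sub_cls)}
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown {name} config key(s): {sorted(unknown)}")
            sections[name] = sub_cls(**raw)
        simulation = data.pop("simulation", {}) or {}
        seed = data.pop("seed", 0)
        if data:
            raise ValueError(f"unknown config key(s): {sorted(data)}")
        return cls(simulation=simulation, seed=seed, **sections)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
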