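"""Pipeline configuration: one YAML file governs every stage.

The multi-window setup (a different observation window per HRV metric,
plus the step and prediction window) is the pipeline's main foot-gun, so
all stages read from a single validated config whose content hash is
embedded in every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .evaluation import ProtocolConfig
from .pipeline import DEFAULT_WO, WindowConfig


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline."""

    # ECG front end
    filter_low_hz: float = 0.5
    filter_high_hz: float = 40.0
    filter_order: int = 2
    qrs_threshold_mult: float = 2.5
    # windows (Wo table, S, Wp)
    wo_per_metric: dict = field(default_factory=lambda: dict(DEFAULT_WO))
    step_s: float = 10.0
    wp_s: float = 60.0
    # SampEn and PSD
    sampen_m: int = 2
    sampen_r_mult: float = 0.2
    resample_hz: float = 4.0
    # cleaning
    sd_mult: float = 3.0
    rel_change: float = 0.30
    max_corrected_fraction: float = 0.02
    # SVM / evaluation
    c_grid: list | None = None
    gamma_grid: list | None = None
    horizon_s: float = 300.0
    n_interictal_train: int | None = None
    # benchmark sizes (used by `run`)
    n_seizures: int = 12
    seizure_duration_s: float = 1020.0
    preictal_onset_s: float = 780.0
    preictal_ramp_s: float = 180.0
    n_interictal_records: int = 4
    interictal_duration_s: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        # delegate window validation; raises ConfigurationError before any work
        self.window_config()
        if not 0 < self.max_corrected_fraction <= 1:
            raise ConfigurationError("max_corrected_fraction must be in (0, 1]")
        if self.horizon_s <= 0:
            raise ConfigurationError("horizon_s must be positive")

    def window_config(self) -> WindowConfig:
        return WindowConfig(
            wo_per_metric=dict(self.wo_per_metric),
            step_s=self.step_s,
            wp_s=self.wp_s,
            sampen_m=self.sampen_m,
            sampen_r_mult=self.sampen_r_mult,
            resample_hz=self.resample_hz,
        )

    def protocol_config(self) -> ProtocolConfig:
        return ProtocolConfig(
            windows=self.window_config(),
            horizon_s=self.horizon_s,
            c_grid=tuple(self.c_grid) if self.c_grid else None,
            gamma_grid=tuple(self.gamma_grid) if self.gamma_grid else None,
            n_interictal_train=self.n_interictal_train,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        """Deterministic short hash of the full configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
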