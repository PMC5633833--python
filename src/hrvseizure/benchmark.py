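"""The bundled synthetic benchmark: simulated seizure and interictal records.

This module fixes the study conditions the end-to-end evaluation runs
under: 12 seizure records, each ending at a seizure onset preceded by a
two-minute sympathetic-activation ramp, plus four half-hour seizure-free
records (2 h total).  Baseline autonomic parameters vary from record to
record (different mean RR, modulation depths and jitter) so the classifier
has to generalize across "patients" rather than memorize one oscillator.

All randomness derives from a single master seed; record seeds stay below
2^31 so they can be reproduced from any small integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RRSeries
from .synthetic import RRGenConfig, gen_rr_series


@dataclass
class BenchmarkConfig:
    """Sizes and physiology of the synthetic benchmark."""

    n_seizures: int = 12
    seizure_duration_s: float = 1020.0  # onset at the record end
    preictal_onset_s: float = 780.0  # autonomic shift starts 4 min before onset
    preictal_ramp_s: float = 180.0
    n_interictal_records: int = 4
    # nominal 30 min each; slightly above so the realized beat coverage
    # (which ends at the last whole beat) still totals >= 2 h over 4 records
    interictal_duration_s: float = 1810.0
    # preictal effect (sympathetic activation): LF up, HF down, tachycardia
    preictal_lf_gain: float = 2.0
    preictal_hf_gain: float = 0.3
    preictal_rr_drop: float = 120.0
    seed: int = 0


def _baseline_params(rng: np.random.Generator) -> dict:
    """Per-record resting autonomic parameters (between-subject variation)."""
    return {
        "base_rr": float(rng.uniform(740.0, 880.0)),
        "lf_amp": float(rng.uniform(25.0, 35.0)),
        "hf_amp": float(rng.uniform(20.0, 30.0)),
        "noise_sd": float(rng.uniform(8.0, 12.0)),
    }


def make_benchmark(
    config: BenchmarkConfig | None = None,
) -> tuple[list[tuple[RRSeries, float]], list[RRSeries]]:
    """Generate the benchmark records.

    Returns ``(seizure_records, interictal_records)`` where each seizure
    record is an ``(RRSeries, onset_s)`` pair with the onset at the record
    end, and each interictal record is a seizure-free RR series.
    """
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(config.seed)

    seizure_records = []
    for _ in range(config.n_seizures):
        params = _baseline_params(rng)
        gen = RRGenConfig(
            duration=config.seizure_duration_s,
            preictal_onset=config.preictal_onset_s,
            preictal_ramp=config.preictal_ramp_s,
            preictal_lf_gain=config.preictal_lf_gain,
            preictal_hf_gain=config.preictal_hf_gain,
            preictal_rr_drop=config.preictal_rr_drop,
            seed=int(rng.integers(0, 2**31 - 1)),
            **params,
        )
        rr, _ = gen_rr_series(gen)
        seizure_records.append((rr, config.seizure_duration_s))

    interictal_records = []
    for _ in range(config.n_interictal_records):
        params = _baseline_params(rng)
        gen = RRGenConfig(
            duration=config.interictal_duration_s,
            seed=int(rng.integers(0, 2**31 - 1)),
            **params,
        )
        rr, _ = gen_rr_series(gen)
        interictal_records.append(rr)

    return seizure_records, interictal_records
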