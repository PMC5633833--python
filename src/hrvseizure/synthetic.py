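"""Synthetic RR-series and ECG generators with known ground truth.

The RR generator produces a tachogram with the oscillatory structure HRV
analysis assumes: a mean level (vagally/sympathetically set RR), a
low-frequency (~0.1 Hz, baroreflex/sympathetic) and a high-frequency
(~0.25 Hz, respiratory sinus arrhythmia) sinusoidal modulation, plus white
beat-to-beat jitter.  A preictal transition is modelled as a linear ramp of
the oscillator gains and of the mean RR: LF modulation rises, HF modulation
falls and the mean RR drops (tachycardia), the qualitative signature of
sympathetic activation in the minutes before a temporal-lobe seizure.

The ECG generator places a stylised P-QRS-T template at each beat time and
adds the three disturbances the front-end filters must remove: slow baseline
wander, 50 Hz powerline interference and white measurement noise.  Both
generators return their ground truth (per-beat state labels, true beat
times) so every downstream stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ParameterError
from .records import ECGRecord, RRSeries

LABEL_INTERICTAL = "interictal"
LABEL_PREICTAL = "preictal"


@dataclass
class RRGenConfig:
    """Parameters of the synthetic tachogram.

    Amplitudes are in ms; the preictal gains are dimensionless multipliers
    applied (after a linear ramp of ``preictal_ramp`` seconds starting at
    ``preictal_onset``) to the LF and HF amplitudes, while
    ``preictal_rr_drop`` (ms) is subtracted from the mean RR.
    """

    duration: float = 600.0
    base_rr: float = 800.0
    lf_amp: float = 30.0
    hf_amp: float = 25.0
    noise_sd: float = 10.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    preictal_onset: float | None = None
    preictal_ramp: float = 120.0
    preictal_lf_gain: float = 2.0
    preictal_hf_gain: float = 0.3
    preictal_rr_drop: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if not 300.0 <= self.base_rr <= 2000.0:
            raise ConfigurationError("base_rr must lie in [300, 2000] ms")
        if min(self.lf_amp, self.hf_amp, self.noise_sd) < 0:
            raise ConfigurationError("amplitudes must be non-negative")
        if self.lf_freq <= 0 or self.hf_freq <= 0:
            raise ConfigurationError("carrier frequencies must be positive")
        if self.preictal_onset is not None:
            if self.preictal_ramp < 0:
                raise ConfigurationError("preictal_ramp must be non-negative")
            if self.preictal_onset + self.preictal_ramp > self.duration:
                raise ConfigurationError(
                    "preictal_onset + preictal_ramp must not exceed duration"
                )


@dataclass
class ECGGenConfig:
    """Parameters of the synthetic ECG waveform."""

    sampling_rate: float = 256.0
    qrs_width: float = 0.08
    qrs_amp: float = 1.0
    p_amp: float = 0.12
    t_amp: float = 0.28
    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.2
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self, min_rr_s: float | None = None) -> None:
        if self.sampling_rate < 128:
            raise ConfigurationError("sampling_rate must be at least 128 Hz")
        if self.qrs_width <= 0:
            raise ConfigurationError("qrs_width must be positive")
        if min_rr_s is not None and self.qrs_width >= min_rr_s:
            raise ConfigurationError("qrs_width must be smaller than the shortest RR")
        if min(self.baseline_wander_amp, self.powerline_amp, self.noise_sd) < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")


def _ramp_weight(t: float, onset: float | None, ramp: float) -> float:
    """Preictal transition weight in [0, 1] at time t."""
    if onset is None or t < onset:
        return 0.0
    if ramp <= 0 or t >= onset + ramp:
        return 1.0
    return (t - onset) / ramp


def gen_rr_series(config: RRGenConfig) -> tuple[RRSeries, np.ndarray]:
    """Generate a synthetic RR series with per-interval state labels.

    The instantaneous interval at beat time ``t`` is

    ``RR(t) = m(t) + a_LF(t)·sin(2π f_LF t + φ1) + a_HF(t)·sin(2π f_HF t + φ2) + ε``

    with ``ε ~ N(0, noise_sd²)`` and phases drawn once from the seeded
    generator.  After ``preictal_onset`` the amplitudes and mean ramp
    linearly over ``preictal_ramp`` seconds toward their preictal values.
    Beat times are the cumulative sums of the intervals.

    Returns
    -------
    (RRSeries, labels)
        ``labels[i]`` is ``"preictal"`` iff interval ``i`` ends at or after
        ``preictal_onset``, else ``"interictal"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    phi1, phi2 = rng.uniform(0.0, 2.0 * np.pi, size=2)

    beat_times = [0.0]
    rr_values: list[float] = []
    t = 0.0
    while True:
        w = _ramp_weight(t, config.preictal_onset, config.preictal_ramp)
        mean_rr = config.base_rr - w * config.preictal_rr_drop
        lf_amp = config.lf_amp * (1.0 + w * (config.preictal_lf_gain - 1.0))
        hf_amp = config.hf_amp * (1.0 + w * (config.preictal_hf_gain - 1.0))
        rr = (
            mean_rr
            + lf_amp * np.sin(2.0 * np.pi * config.lf_freq * t + phi1)
            + hf_amp * np.sin(2.0 * np.pi * config.hf_freq * t + phi2)
        )
        if config.noise_sd > 0:
            rr += rng.normal(0.0, config.noise_sd)
        if rr <= 0:
            raise ConfigurationError("configuration produced a non-positive RR")
        t_next = t + rr / 1000.0
        if t_next > config.duration + 1e-9:
            break
        beat_times.append(t_next)
        rr_values.append(rr)
        t = t_next

    if len(rr_values) < 1:
        raise ConfigurationError("duration too short to fit a single beat")
    series = RRSeries(np.array(beat_times), np.array(rr_values))
    onset = config.preictal_onset
    if onset is None:
        labels = np.full(len(series), LABEL_INTERICTAL, dtype=object)
    else:
        labels = np.where(
            series.interval_times >= onset - 1e-12, LABEL_PREICTAL, LABEL_INTERICTAL
        ).astype(object)
    return series, labels


def inject_ectopics(
    rr: RRSeries,
    rate: float,
    seed: int = 0,
    indices: Sequence[int] | None = None,
) -> tuple[RRSeries, list[int]]:
    """Insert early-beat/compensatory-pause ectopic pairs into an RR series.

    At each event index ``i``, ``rr[i]`` is halved (premature beat) and
    ``rr[i+1]`` is scaled by 1.5 (compensatory pause); beat times are then
    recomputed from the modified intervals.  ``rate`` is in events per
    minute; the number of events is ``round(rate · duration_min)`` and the
    event positions are drawn from the seeded generator unless ``indices``
    pins them explicitly.

    Returns the modified series and the sorted list of event indices.
    """
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    n = len(rr)
    if indices is None:
        duration_min = rr.duration / 60.0
        n_events = int(round(rate * duration_min))
        if n_events == 0:
            return rr.copy(), []
        candidates = np.arange(0, n - 1)
        if n_events > (n - 1) // 2:
            raise ParameterError("ectopic rate too high: events would overlap")
        rng = np.random.default_rng(seed)
        chosen: list[int] = []
        for idx in rng.permutation(candidates):
            if all(abs(idx - c) > 1 for c in chosen):
                chosen.append(int(idx))
                if len(chosen) == n_events:
                    break
        if len(chosen) < n_events:
            raise ParameterError("ectopic rate too high: events would overlap")
        indices = sorted(chosen)
    else:
        indices = sorted(int(i) for i in indices)
        if any(i < 0 or i >= n - 1 for i in indices):
            raise ParameterError("ectopic index out of range")
        if any(b - a <= 1 for a, b in zip(indices, indices[1:])):
            raise ParameterError("ectopic events overlap")

    new_rr = rr.rr.copy()
    for i in indices:
        new_rr[i] *= 0.5
        new_rr[i + 1] *= 1.5
    beat_times = rr.beat_times[0] + np.concatenate(
        [[0.0], np.cumsum(new_rr) / 1000.0]
    )
    return RRSeries(beat_times, new_rr), list(indices)


def _add_bump(
    signal: np.ndarray, t: np.ndarray, center: float, amp: float, sigma: float
) -> None:
    # restrict to ±5σ to keep placement O(beats), not O(beats·samples)
    fs = 1.0 / (t[1] - t[0])
    lo = max(0, int((center - 5 * sigma) * fs))
    hi = min(t.size, int((center + 5 * sigma) * fs) + 1)
    if hi <= lo:
        return
    seg = t[lo:hi]
    signal[lo:hi] += amp * np.exp(-0.5 * ((seg - center) / sigma) ** 2)


def gen_ecg(rr: RRSeries, config: ECGGenConfig) -> tuple[ECGRecord, np.ndarray]:
    """Render an RR series as a synthetic single-lead ECG.

    A template beat — Gaussian R wave of width ``qrs_width`` flanked by
    smaller P and T bumps — is placed at every beat time; baseline wander,
    powerline interference and white noise are then added.

    Returns the record and the true beat (R-peak) times for detector scoring.
    """
    min_rr_s = float(np.min(rr.rr)) / 1000.0
    config.validate(min_rr_s=min_rr_s)
    fs = config.sampling_rate
    n_samples = int(round((rr.beat_times[-1] - rr.beat_times[0]) * fs))
    if n_samples < 2:
        raise ConfigurationError("RR series too short to render an ECG")
    t = rr.beat_times[0] + np.arange(n_samples) / fs

    x = np.zeros(n_samples)
    r_sigma = config.qrs_width / 6.0  # ±3σ spans the QRS complex
    for tb in rr.beat_times:
        _add_bump(x, t, tb - 0.18, config.p_amp * config.qrs_amp, 0.025)
        _add_bump(x, t, tb, config.qrs_amp, r_sigma)
        _add_bump(x, t, tb + 0.22, config.t_amp * config.qrs_amp, 0.05)

    rng = np.random.default_rng(config.seed)
    if config.baseline_wander_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += config.baseline_wander_amp * np.sin(
            2.0 * np.pi * config.baseline_wander_freq * t + phase
        )
    if config.powerline_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += config.powerline_amp * np.sin(
            2.0 * np.pi * config.powerline_freq * t + phase
        )
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=n_samples)

    record = ECGRecord(x, fs, start_time=float(rr.beat_times[0]))
    return record, rr.beat_times.copy()
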