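"""Core in-memory containers: raw ECG records and RR-interval series.

An :class:`ECGRecord` is a uniformly sampled single-lead voltage trace.
An :class:`RRSeries` is the beat-time / RR-interval representation that all
HRV analysis operates on: ``rr[i]`` is the interval (ms) ending at
``beat_times[i + 1]`` (s), so ``len(rr) == len(beat_times) - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

FLAG_NORMAL = "normal"
FLAG_CORRECTED = "corrected"


@dataclass
class ECGRecord:
    """Single-lead ECG sample stream.

    Parameters
    ----------
    samples
        Voltage samples in mV.
    sampling_rate
        Sampling frequency in Hz (> 0).
    start_time
        Time of the first sample, seconds.
    annotations
        Optional ``(label, time_s)`` event markers (e.g. seizure onsets).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    annotations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise ParameterError("an ECG record needs at least 2 samples")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class RRSeries:
    """Beat times (s) plus consecutive RR intervals (ms) with quality flags.

    Invariants: ``beat_times`` strictly increasing, all ``rr > 0`` and
    ``len(rr) == len(beat_times) - 1``; ``flags[i]`` marks interval ``i`` as
    ``"normal"`` or ``"corrected"``.
    """

    beat_times: np.ndarray
    rr: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.rr.size, FLAG_NORMAL, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if self.beat_times.size < 2:
            raise ParameterError("an RR series needs at least 2 beat times")
        if self.rr.size != self.beat_times.size - 1:
            raise ParameterError("len(rr) must equal len(beat_times) - 1")
        if self.flags.size != self.rr.size:
            raise ParameterError("one quality flag per interval required")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ParameterError("beat_times must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ParameterError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.rr.size

    @property
    def interval_times(self) -> np.ndarray:
        """Time (s) at which each interval ends — the tachogram abscissa."""
        return self.beat_times[1:]

    @property
    def duration(self) -> float:
        """Span covered by the series, seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def copy(self) -> "RRSeries":
        return RRSeries(self.beat_times.copy(), self.rr.copy(), self.flags.copy())
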