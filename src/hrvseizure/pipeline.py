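"""Sliding-window prediction matrices and covariance eigen-features.

A prediction matrix X ∈ R^{p×n} stacks the p HRV metrics evaluated at n
column times spaced S seconds apart and ending at an anchor time; each
metric looks back over its own observation window Wo (the spectral metrics
need a longer history than the time-domain ones).  The classifier input Λ
is the largest eigenvalue of X's sample covariance matrix R plus the first
p−1 components of the corresponding unit-norm eigenvector — a snapshot of
how much, and along which metric combination, the HRV state is moving.

The construction is strictly causal: no RR data after the anchor is read,
and a matrix is refused (never padded) when the history is incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import features as feat
from .errors import ConfigurationError, CoverageError, ParameterError
from .records import RRSeries

DEFAULT_WO = {
    "sdnn": 60.0,
    "rmssd": 60.0,
    "lf": 180.0,
    "hf": 180.0,
    "sampen": 60.0,
    "csi": 60.0,
    "cvi": 60.0,
}


@dataclass
class WindowConfig:
    """Observation-window table plus step and prediction-window lengths.

    ``wo_per_metric`` maps each metric to its observation window Wo (s);
    ``step_s`` is the slide S between columns and ``wp_s`` the prediction
    window Wp, so a matrix has ``n = wp_s / step_s`` columns.
    """

    wo_per_metric: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WO))
    step_s: float = 10.0
    wp_s: float = 60.0
    sampen_m: int = 2
    sampen_r_mult: float = 0.2
    resample_hz: float = 4.0

    def __post_init__(self) -> None:
        if self.step_s <= 0 or self.wp_s <= 0:
            raise ConfigurationError("step_s and wp_s must be positive")
        ratio = self.wp_s / self.step_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("wp_s must be divisible by step_s")
        if round(ratio) < 2:
            raise ConfigurationError("need at least 2 columns (wp_s >= 2*step_s)")
        unknown = set(self.wo_per_metric) - set(feat.METRIC_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown metrics in wo table: {sorted(unknown)}")
        if set(self.wo_per_metric) != set(feat.METRIC_NAMES):
            raise ConfigurationError("wo table must cover all seven metrics")
        if min(self.wo_per_metric.values()) <= 0:
            raise ConfigurationError("observation windows must be positive")

    @property
    def n_columns(self) -> int:
        return int(round(self.wp_s / self.step_s))

    @property
    def max_wo(self) -> float:
        return max(self.wo_per_metric.values())

    @property
    def history_s(self) -> float:
        """RR history required behind an anchor: max(Wo) + Wp."""
        return self.max_wo + self.wp_s


@dataclass
class PredictionMatrix:
    """p×n matrix of windowed HRV metric values ending at an anchor."""

    x: np.ndarray
    metric_names: tuple[str, ...]
    column_times: np.ndarray
    anchor_time: float


@dataclass
class EigenFeature:
    """Λ = [λ_max, v_1 … v_{p−1}]: the classifier input at one anchor."""

    lambda_max: float
    v: np.ndarray
    anchor_time: float

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([[self.lambda_max], self.v])


def _window_rr(rr: RRSeries, t_lo: float, t_hi: float) -> np.ndarray:
    """RR values of intervals ending in the half-open window (t_lo, t_hi]."""
    ends = rr.interval_times
    lo = np.searchsorted(ends, t_lo, side="right")
    hi = np.searchsorted(ends, t_hi, side="right")
    return rr.rr[lo:hi], rr.interval_times[lo:hi]


def _metric_value(
    name: str, rr_win: np.ndarray, times_win: np.ndarray, config: WindowConfig
) -> float:
    if name == "sdnn":
        return feat.sdnn(rr_win)
    if name == "rmssd":
        return feat.rmssd(rr_win)
    if name == "lf":
        return feat.band_power(times_win, rr_win, *feat.LF_BAND, config.resample_hz)
    if name == "hf":
        return feat.band_power(times_win, rr_win, *feat.HF_BAND, config.resample_hz)
    if name == "sampen":
        sd = np.std(rr_win, ddof=1)
        r = config.sampen_r_mult * sd if sd > 0 else None
        value = feat.sampen(rr_win, m=config.sampen_m, r=r)
        if np.isinf(value):
            # no (m+1)-template matches in this window: cap at the largest
            # entropy resolvable from the available template pairs so the
            # covariance stays finite
            n_t = rr_win.size - config.sampen_m
            value = float(np.log(max(n_t * (n_t - 1) / 2, 2)))
        return value
    if name == "csi":
        L, T = feat.lorenz_axes(rr_win)
        return feat.csi(L, T)
    if name == "cvi":
        L, T = feat.lorenz_axes(rr_win)
        return feat.cvi(L, T)
    raise ParameterError(f"unknown metric {name!r}")


def build_prediction_matrix(
    rr: RRSeries, anchor_time: float, config: WindowConfig | None = None
) -> PredictionMatrix:
    """Fill the p×n prediction matrix anchored at ``anchor_time``.

    Column j ends at ``t_j = anchor_time - (n-1-j)·S``; each metric row is
    computed from the RR intervals ending in ``(t_j - Wo_metric, t_j]``.
    Raises :class:`CoverageError` when the series does not span
    ``[anchor - max(Wo) - Wp, anchor]``.
    """
    config = config or WindowConfig()
    n = config.n_columns
    earliest_needed = anchor_time - config.history_s
    if rr.beat_times[0] > earliest_needed + 1e-9:
        raise CoverageError(
            f"RR series starts at {rr.beat_times[0]:.1f} s but history from "
            f"{earliest_needed:.1f} s is required for anchor {anchor_time:.1f} s"
        )
    if rr.beat_times[-1] < anchor_time - 1e-9:
        raise CoverageError(
            f"RR series ends at {rr.beat_times[-1]:.1f} s, before the anchor "
            f"{anchor_time:.1f} s"
        )

    column_times = anchor_time - config.step_s * np.arange(n - 1, -1, -1)
    x = np.empty((len(feat.METRIC_NAMES), n))
    for j, t_j in enumerate(column_times):
        for i, name in enumerate(feat.METRIC_NAMES):
            wo = config.wo_per_metric[name]
            rr_win, times_win = _window_rr(rr, t_j - wo, t_j)
            x[i, j] = _metric_value(name, rr_win, times_win, config)
    return PredictionMatrix(
        x=x,
        metric_names=feat.METRIC_NAMES,
        column_times=column_times,
        anchor_time=float(anchor_time),
    )


def covariance(matrix: PredictionMatrix | np.ndarray) -> np.ndarray:
    """Sample covariance (n−1 denominator) between metric rows across columns.

    Neither the rows nor the result are normalized; the diagonal holds the
    per-metric variances and ``trace(R)`` equals their sum exactly.
    """
    x = matrix.x if isinstance(matrix, PredictionMatrix) else np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ParameterError("covariance needs a 2-D matrix with at least 2 columns")
    return np.cov(x, rowvar=True, ddof=1)


def eigen_feature(
    r: np.ndarray, anchor_time: float = 0.0, sym_tol: float = 1e-8
) -> EigenFeature:
    """Λ from the covariance matrix R: largest eigenvalue + leading eigenvector.

    The eigenvector is unit-norm with a deterministic sign (its largest-
    magnitude component is made positive); its *last* component is dropped,
    recoverable up to sign from the unit-norm constraint, so that
    ``len(Λ) == p``.
    """
    r = np.asarray(r, dtype=float)
    scale = max(1.0, float(np.max(np.abs(r))))
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ParameterError("R must be square")
    if not np.allclose(r, r.T, atol=sym_tol * scale):
        raise ParameterError("R must be symmetric")
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    lam = float(w[-1])
    vec = v[:, -1]
    pivot = int(np.argmax(np.abs(vec)))
    if vec[pivot] < 0:
        vec = -vec
    return EigenFeature(lambda_max=lam, v=vec[:-1].copy(), anchor_time=anchor_time)


def stream_features(
    rr: RRSeries, config: WindowConfig | None = None
) -> Iterator[EigenFeature]:
    """Eigen-features at every feasible anchor, sliding by S seconds.

    The first anchor sits ``max(Wo) + Wp`` after the first beat (the
    observation window then acts as a circular buffer, dropping the oldest
    S seconds at each step); the last anchor is the final beat time.
    """
    config = config or WindowConfig()
    if rr.duration < config.history_s:
        raise CoverageError(
            f"series of {rr.duration:.1f} s shorter than the "
            f"{config.history_s:.1f} s needed for one feature"
        )
    t = rr.beat_times[0] + config.history_s
    end = rr.beat_times[-1]
    while t <= end + 1e-9:
        matrix = build_prediction_matrix(rr, t, config)
        yield eigen_feature(covariance(matrix), anchor_time=t)
        t += config.step_s
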