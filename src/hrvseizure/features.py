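"""The seven HRV metrics: SDNN, RMSSD, LF, HF, SampEn, CSI, CVI.

Time-domain metrics operate on the raw RR values; spectral metrics operate
on the tachogram (RR versus interval-end time) after mean removal and cubic
resampling to a uniform 4 Hz grid, with band power integrated from a
Hann-windowed periodogram.  The Poincaré/Lorenz indices use the SD1/SD2
dispersion definition of the plot axes: ``T = 4·SD1`` across the identity
line, ``L = 4·SD2`` along it, giving the cardiosympathetic index
``CSI = L/T`` and the cardiovagal index ``CVI = log10(L·T)``.

Sample entropy follows the Richman–Moorman template-matching definition
with defaults ``m = 2`` and ``r = 0.2·SD`` of the window; matches use a
strict Chebyshev criterion (distance < r) with self-matches excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

from .errors import InsufficientDataError, ParameterError
from .records import RRSeries

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

METRIC_NAMES = ("sdnn", "rmssd", "lf", "hf", "sampen", "csi", "cvi")


@dataclass
class HRVFeatureVector:
    """The seven metrics of one observation window."""

    sdnn: float
    rmssd: float
    lf: float
    hf: float
    sampen: float
    csi: float
    cvi: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])


def sdnn(rr: np.ndarray) -> float:
    """Standard deviation (n-1 denominator) of the RR intervals, ms."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise InsufficientDataError("SDNN needs at least 2 intervals")
    return float(np.std(rr, ddof=1))


def rmssd(rr: np.ndarray) -> float:
    """Root mean square of successive RR differences, ms."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise InsufficientDataError("RMSSD needs at least 3 intervals")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d**2)))


def band_power(
    beat_times: np.ndarray,
    rr: np.ndarray,
    f_lo: float,
    f_hi: float,
    resample_hz: float = 4.0,
) -> float:
    """Tachogram spectral power in [f_lo, f_hi), ms².

    The (interval-end time, RR) tachogram is mean-detrended, resampled to a
    uniform grid by cubic interpolation, and its one-sided Hann periodogram
    integrated over the band.  The window must span at least three cycles
    of the slowest band component and contain at least 8 beats.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if not 0 < f_lo < f_hi:
        raise ParameterError("band edges must satisfy 0 < f_lo < f_hi")
    if rr.size < 8:
        raise InsufficientDataError("band power needs at least 8 beats")
    span = beat_times[-1] - beat_times[0]
    if span < 3.0 / f_lo:
        raise InsufficientDataError(
            f"window of {span:.1f} s is shorter than 3 cycles at {f_lo} Hz"
        )
    x = rr - np.mean(rr)
    interp = interp1d(beat_times, x, kind="cubic")
    n = int(span * resample_hz)
    grid = beat_times[0] + np.arange(n) / resample_hz
    xs = interp(grid)
    xs = xs - np.mean(xs)
    freqs, psd = sps.periodogram(xs, fs=resample_hz, window="hann", detrend=False)
    df = freqs[1] - freqs[0]
    mask = (freqs >= f_lo) & (freqs < f_hi)
    return float(np.sum(psd[mask]) * df)


def sampen(rr: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy of the RR sequence.

    ``-ln(A/B)`` where B counts pairs of length-``m`` templates and A pairs
    of length-``m+1`` templates within Chebyshev distance ``< r``
    (self-matches excluded).  ``r`` defaults to ``0.2·SD`` of the window.
    Returns ``inf`` when no (m+1)-matches exist, and 0.0 for a constant
    window (perfectly regular by convention).
    """
    x = np.asarray(rr, dtype=float)
    if x.size < m + 2:
        raise InsufficientDataError(f"SampEn needs at least m+2={m + 2} intervals")
    if r is None:
        sd = np.std(x, ddof=1)
        if sd == 0.0:
            return 0.0
        r = 0.2 * sd
    if r <= 0:
        raise ParameterError("tolerance r must be positive")
    if np.ptp(x) == 0.0:
        return 0.0

    n_templates = x.size - m  # same template count for both lengths
    idx = np.arange(n_templates)
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)

    # pairwise Chebyshev distances, i < j only
    db = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=-1)
    da = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=-1)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(db[iu] < r))
    a = int(np.count_nonzero(da[iu] < r))
    if b == 0 or a == 0:
        return math.inf
    return float(-math.log(a / b))


def lorenz_axes(rr: np.ndarray) -> tuple[float, float]:
    """Longitudinal (L) and transverse (T) axis lengths of the Lorenz plot.

    From the scatter of RR(n+1) against RR(n): ``T = 4·SD1`` where SD1 is
    the dispersion perpendicular to the identity line, ``L = 4·SD2`` along
    it.  Returns ``(L, T)`` in ms; a constant series gives ``(0, 0)``.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Lorenz axes need at least 3 intervals")
    diff = (x[1:] - x[:-1]) / np.sqrt(2.0)
    summ = (x[1:] + x[:-1]) / np.sqrt(2.0)
    sd1 = float(np.std(diff, ddof=1))
    sd2 = float(np.std(summ, ddof=1))
    return 4.0 * sd2, 4.0 * sd1


def csi(L: float, T: float) -> float:
    """Cardiosympathetic index L/T."""
    if T <= 0:
        raise ParameterError("CSI undefined for non-positive transverse axis")
    return L / T


def cvi(L: float, T: float) -> float:
    """Cardiovagal index log10(L·T)."""
    if L <= 0 or T <= 0:
        raise ParameterError("CVI undefined for non-positive axes")
    return float(np.log10(L * T))


def compute_feature_vector(
    window: RRSeries,
    m: int = 2,
    r_mult: float = 0.2,
    resample_hz: float = 4.0,
) -> HRVFeatureVector:
    """All seven metrics on one observation window.

    Degenerate (constant) windows yield NaN for CSI and CVI, the documented
    sentinel for the undefined Lorenz ratio.  When invoked through the
    sliding-window pipeline, LF and HF are computed from their own longer
    windows instead.
    """
    rr = window.rr
    sd = np.std(rr, ddof=1)
    L, T = lorenz_axes(rr)
    return HRVFeatureVector(
        sdnn=sdnn(rr),
        rmssd=rmssd(rr),
        lf=band_power(window.interval_times, rr, *LF_BAND, resample_hz=resample_hz),
        hf=band_power(window.interval_times, rr, *HF_BAND, resample_hz=resample_hz),
        sampen=sampen(rr, m=m, r=r_mult * sd if sd > 0 else None),
        csi=csi(L, T) if T > 0 else math.nan,
        cvi=cvi(L, T) if (L > 0 and T > 0) else math.nan,
    )
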