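"""ECG front end: band-pass filtering, wavelet QRS detection, RR extraction.

The detector follows the classic wavelet recipe: a stationary wavelet
transform of the (filtered) signal, a detection function built from the
squared detail coefficients at the dyadic scales whose pass-bands overlap
the core QRS energy range, an adaptive threshold proportional to the
running RMS of that function's magnitude, a 200 ms refractory period, and
refinement of each detection to the nearest raw-signal extremum.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientDataError, ParameterError
from .records import ECGRecord, RRSeries

#: nominal band (Hz) of an SWT detail level d at sampling rate fs is
#: [fs / 2^(d+1), fs / 2^d]; levels overlapping this range carry the bulk
#: of QRS energy while excluding T waves and keeping the energy compact
_QRS_BAND = (8.0, 32.0)


def bandpass_filter(
    ecg: ECGRecord, low_cut: float = 0.5, high_cut: float = 40.0, order: int = 2
) -> ECGRecord:
    """Zero-phase Butterworth band-pass (high-pass then low-pass).

    Both filters are of the given order and applied forward-backward
    (``sosfiltfilt``), removing baseline wander below ``low_cut`` and
    muscle/powerline artifacts above ``high_cut`` without phase distortion.
    """
    nyq = ecg.sampling_rate / 2.0
    if not 0.0 < low_cut < high_cut < nyq:
        raise ParameterError(
            f"cutoffs must satisfy 0 < low ({low_cut}) < high ({high_cut}) "
            f"< Nyquist ({nyq})"
        )
    sos_hp = sps.butter(order, low_cut, btype="highpass", fs=ecg.sampling_rate, output="sos")
    sos_lp = sps.butter(order, high_cut, btype="lowpass", fs=ecg.sampling_rate, output="sos")
    x = sps.sosfiltfilt(sos_hp, ecg.samples)
    x = sps.sosfiltfilt(sos_lp, x)
    return ECGRecord(x, ecg.sampling_rate, ecg.start_time, list(ecg.annotations))


def _swt_levels(fs: float) -> list[int]:
    """SWT detail levels whose nominal bands overlap the QRS band."""
    levels = []
    for d in range(1, 9):
        lo, hi = fs / 2 ** (d + 1), fs / 2**d
        if hi > _QRS_BAND[0] and lo < _QRS_BAND[1]:
            levels.append(d)
    return levels


def qrs_detection_function(ecg: ECGRecord, wavelet: str = "db2") -> np.ndarray:
    """Squared-magnitude SWT detection function, lightly smoothed."""
    x = ecg.samples - np.mean(ecg.samples)
    levels = _swt_levels(ecg.sampling_rate)
    max_level = max(levels)
    block = 2**max_level
    pad = (-x.size) % block
    if pad:
        x = np.pad(x, (0, pad), mode="reflect")
    coeffs = pywt.swt(x, wavelet, level=max_level, trim_approx=True, norm=False)
    # trim_approx=True -> [approx, cD_max, ..., cD1]
    details = {max_level - i + 1: coeffs[i] for i in range(1, len(coeffs))}
    d = np.zeros_like(x)
    for lev in levels:
        d += details[lev] ** 2
    d = d[: ecg.samples.size]
    smooth = max(1, int(0.05 * ecg.sampling_rate))
    return uniform_filter1d(d, smooth)


def detect_qrs(
    ecg: ECGRecord,
    wavelet: str = "db2",
    threshold_mult: float = 2.5,
    refractory_s: float = 0.2,
    refine_s: float = 0.06,
) -> np.ndarray:
    """Detect R-peak times (s) in an ECG record.

    The adaptive threshold is ``threshold_mult`` times the running RMS of
    the detection function (2 s window).  No two beats are reported closer
    than ``refractory_s``; each detection is refined to the largest
    absolute raw-signal excursion within ``±refine_s``.
    """
    if ecg.duration < 2.0:
        raise InsufficientDataError("record shorter than 2 s")
    fs = ecg.sampling_rate
    n = ecg.samples.size

    # reflect-pad so beats at the record edges produce findable local maxima
    pad = int(0.5 * fs)
    padded = ECGRecord(
        np.pad(ecg.samples, pad, mode="reflect"), fs, ecg.start_time - pad / fs
    )
    d = qrs_detection_function(padded, wavelet=wavelet)
    # d is an energy; threshold its magnitude sqrt(d) against the running
    # RMS of that magnitude (sqrt of the 2 s running mean energy)
    e = np.sqrt(d)
    rms_win = int(2.0 * fs)
    running_rms = np.sqrt(uniform_filter1d(d, rms_win)) + 1e-30
    threshold = threshold_mult * running_rms

    distance = max(1, int(refractory_s * fs))
    peaks, _ = sps.find_peaks(e, height=threshold, distance=distance)
    peaks = peaks[(peaks >= pad // 2) & (peaks < n + pad + pad // 2)]
    if peaks.size == 0:
        warnings.warn("no QRS complexes detected", stacklevel=2)
        return np.array([])

    # refine to the raw-signal extremum (largest |deviation from local baseline|)
    half = max(1, int(refine_s * fs))
    baseline = uniform_filter1d(padded.samples, int(0.5 * fs))
    dev = np.abs(padded.samples - baseline)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(padded.samples.size, p + half + 1)
        refined.append(lo + int(np.argmax(dev[lo:hi])))
    refined = np.unique([min(max(q, pad), n + pad - 1) for q in refined])

    # enforce refractory after refinement, keeping the stronger beat
    kept: list[int] = []
    for idx in refined:
        if kept and (idx - kept[-1]) < distance:
            if dev[idx] > dev[kept[-1]]:
                kept[-1] = int(idx)
        else:
            kept.append(int(idx))
    return ecg.start_time + (np.array(kept) - pad) / fs


def extract_rr(beat_times: np.ndarray) -> RRSeries:
    """Convert strictly increasing beat times (s) into an RR series (ms)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise InsufficientDataError("need at least 2 beat times")
    if np.any(np.diff(beat_times) <= 0):
        raise ParameterError("beat times must be strictly increasing")
    rr = np.diff(beat_times) * 1000.0
    return RRSeries(beat_times, rr)


def ecg_to_rr(
    ecg: ECGRecord,
    low_cut: float = 0.5,
    high_cut: float = 40.0,
    order: int = 2,
    **detector_kwargs,
) -> RRSeries:
    """Full front end: filter, detect QRS, extract the RR series."""
    filtered = bandpass_filter(ecg, low_cut=low_cut, high_cut=high_cut, order=order)
    beats = detect_qrs(filtered, **detector_kwargs)
    return extract_rr(beats)
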