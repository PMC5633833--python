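"""Artifact/ectopic detection and repair on RR series, plus the quality gate.

An interval is flagged when it both deviates from the segment mean by more
than ``sd_mult`` sample standard deviations *and* changes by more than
``rel_change`` relative to the previous interval (the conjunction is the
default; a disjunction mode is available because many HRV tools use OR).
Flagged values are removed and refilled by a cubic spline through the
surviving (time, RR) points.  Recordings in which the corrected fraction
reaches 2% are rejected outright, since interpolation beyond that level
biases every downstream HRV metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, ParameterError
from .records import FLAG_CORRECTED, RRSeries

DEFAULT_QUALITY_THRESHOLD = 0.02


@dataclass
class CleaningReport:
    """Outcome of one cleaning pass over an RR segment."""

    flagged_indices: list[int]
    corrected_fraction: float
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "flagged_indices": [int(i) for i in self.flagged_indices],
            "corrected_fraction": float(self.corrected_fraction),
            "accepted": bool(self.accepted),
        }


def flag_artifacts(
    rr: RRSeries,
    sd_mult: float = 3.0,
    rel_change: float = 0.30,
    mode: str = "and",
) -> np.ndarray:
    """Indices of intervals flagged as artifacts/ectopic beats.

    Interval ``i`` is suspect on the dispersion rule when
    ``|rr_i - mean| > sd_mult * SD`` (sample SD over the whole segment) and
    on the step rule when ``|rr_i - rr_{i-1}| / rr_{i-1} > rel_change``.
    The first interval has no predecessor and is judged on the dispersion
    rule alone.  ``mode`` combines the two rules with ``"and"`` (default)
    or ``"or"``.
    """
    if mode not in ("and", "or"):
        raise ParameterError("mode must be 'and' or 'or'")
    x = rr.rr
    if x.size < 3:
        raise InsufficientDataError("need at least 3 intervals to flag artifacts")
    sd = np.std(x, ddof=1)
    dev = np.abs(x - np.mean(x)) > sd_mult * sd
    step = np.zeros(x.size, dtype=bool)
    step[1:] = np.abs(np.diff(x)) / x[:-1] > rel_change
    if mode == "and":
        flagged = dev.copy()
        flagged[1:] &= step[1:]
    else:
        flagged = dev | step
    return np.flatnonzero(flagged)


def correct_artifacts(
    rr: RRSeries,
    flagged: np.ndarray,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> tuple[RRSeries, CleaningReport]:
    """Replace flagged intervals by cubic-spline interpolation.

    The spline is fitted through the surviving (beat index, RR) points and
    evaluated at the removed indices — the beat index is the natural
    abscissa of the tachogram and keeps the repair exact for polynomial
    trends (the interval *end time* is itself distorted by the artifact
    being repaired).  Beat times are left untouched, so only the flagged
    values change; unflagged intervals are never altered.
    """
    flagged = np.asarray(flagged, dtype=int)
    n = len(rr)
    if flagged.size and (flagged.min() < 0 or flagged.max() >= n):
        raise ParameterError("flagged index out of range")
    flagged = np.unique(flagged)
    if flagged.size >= n:
        raise ParameterError("cannot correct a series with every interval flagged")

    out = rr.copy()
    if flagged.size:
        keep = np.setdiff1d(np.arange(n), flagged)
        if keep.size < 2:
            raise ParameterError("too few surviving points for spline interpolation")
        spline = CubicSpline(keep.astype(float), rr.rr[keep])
        out.rr[flagged] = spline(flagged.astype(float))
        out.flags[flagged] = FLAG_CORRECTED

    fraction = flagged.size / n
    report = CleaningReport(
        flagged_indices=list(map(int, flagged)),
        corrected_fraction=float(fraction),
        accepted=quality_gate_fraction(fraction, quality_threshold),
    )
    return out, report


def quality_gate_fraction(
    fraction: float, threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> bool:
    """Strict gate: accepted iff corrected fraction is *below* threshold."""
    return fraction < threshold


def quality_gate(
    report: CleaningReport, threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> bool:
    """Accept a recording iff its corrected fraction is strictly below threshold."""
    return quality_gate_fraction(report.corrected_fraction, threshold)


def clean_rr(
    rr: RRSeries,
    sd_mult: float = 3.0,
    rel_change: float = 0.30,
    mode: str = "and",
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> tuple[RRSeries, CleaningReport]:
    """Flag and correct in one deterministic pass (no iterative re-flagging)."""
    flagged = flag_artifacts(rr, sd_mult=sd_mult, rel_change=rel_change, mode=mode)
    return correct_artifacts(rr, flagged, quality_threshold=quality_threshold)
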