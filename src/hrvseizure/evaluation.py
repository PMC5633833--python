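"""Evaluation protocol: streaming warnings, horizon sensitivity, FP/h, LOOCV.

A *warning* is a positive classifier output on the eigen-feature stream; a
warning *event* is the onset of a run of positives.  A seizure counts as
detected when at least one warning falls in ``[onset - horizon, onset)``
(the warning must precede the onset strictly).  The false-positive rate is
the number of warning events per hour on verified seizure-free recordings.

The leave-one-seizure-out protocol trains, for each seizure, on every
other seizure's preictal eigen-feature plus a pool of interictal training
features, then scores detection on the held-out record; each fold's model
is also run over held-out interictal recordings to accumulate FP/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifier as clf
from .errors import ParameterError
from .pipeline import WindowConfig, build_prediction_matrix, covariance, eigen_feature, stream_features
from .records import RRSeries


@dataclass
class WarningSeries:
    """Positive classifier outputs on one record."""

    times: np.ndarray  # all positive-output anchor times, s
    events: np.ndarray  # onsets of positive runs, s
    record_duration: float  # hours

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if self.record_duration <= 0:
            raise ParameterError("record_duration must be positive")


@dataclass
class EvaluationReport:
    """Sensitivity over the prediction horizon plus FP/h."""

    sensitivity: float
    detected: int
    total_seizures: int
    fp_per_hour: float
    horizon_s: float
    per_seizure: list = field(default_factory=list)
    cv_accuracy: float | None = None
    c: float | None = None
    gamma: float | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "detected": self.detected,
            "total_seizures": self.total_seizures,
            "fp_per_hour": self.fp_per_hour,
            "horizon_s": self.horizon_s,
            "per_seizure": self.per_seizure,
            "cv_accuracy": self.cv_accuracy,
            "c": self.c,
            "gamma": self.gamma,
        }


def warnings_from_outputs(
    anchor_times: np.ndarray, positive: np.ndarray, record_duration_h: float
) -> WarningSeries:
    """Build a WarningSeries from per-anchor classifier outputs.

    An event is a positive output whose immediately preceding output was
    negative (or the first output, if positive).
    """
    anchor_times = np.asarray(anchor_times, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    times = anchor_times[positive]
    prev = np.concatenate([[False], positive[:-1]])
    events = anchor_times[positive & ~prev]
    return WarningSeries(times=times, events=events, record_duration=record_duration_h)


def detect_stream(
    model: clf.SVMModel, rr: RRSeries, config: WindowConfig | None = None
) -> WarningSeries:
    """Run the eigen-feature stream through the classifier on one record."""
    config = config or WindowConfig()
    feats = list(stream_features(rr, config))
    anchors = np.array([f.anchor_time for f in feats])
    vectors = np.array([f.vector for f in feats])
    labels, _ = clf.predict_many(model, vectors)
    return warnings_from_outputs(
        anchors, labels == clf.PREICTAL, rr.duration / 3600.0
    )


def sensitivity(
    warnings: list[WarningSeries], onsets: list[float], horizon_s: float = 300.0
) -> tuple[float, int, int]:
    """Fraction of seizures with >= 1 warning in [onset - horizon, onset).

    One WarningSeries per seizure record; any positive output (not only an
    event onset) inside the half-open horizon counts.
    """
    if len(onsets) == 0:
        raise ParameterError("sensitivity needs at least one seizure")
    if len(warnings) != len(onsets):
        raise ParameterError("one warning series per seizure required")
    detected = 0
    for ws, onset in zip(warnings, onsets):
        hit = np.any((ws.times >= onset - horizon_s) & (ws.times < onset))
        detected += int(hit)
    return detected / len(onsets), detected, len(onsets)


def fp_rate(warnings: list[WarningSeries], unit: str = "events") -> float:
    """False positives per hour across seizure-free records.

    ``unit="events"`` (default) counts onsets of positive runs, so a
    sustained false alarm counts once; ``unit="outputs"`` counts every
    positive output, which changes the rate materially on flickering
    classifiers.
    """
    if unit not in ("events", "outputs"):
        raise ParameterError("unit must be 'events' or 'outputs'")
    total_hours = sum(ws.record_duration for ws in warnings)
    if total_hours <= 0:
        raise ParameterError("total duration must be positive")
    total = sum(
        (ws.events if unit == "events" else ws.times).size for ws in warnings
    )
    return total / total_hours


@dataclass
class ProtocolConfig:
    """Settings of the leave-one-seizure-out evaluation."""

    windows: WindowConfig = field(default_factory=WindowConfig)
    horizon_s: float = 300.0
    c: float | None = None  # fixed (C, γ); None -> grid search
    gamma: float | None = None
    c_grid: tuple[float, ...] | None = None
    gamma_grid: tuple[float, ...] | None = None
    n_interictal_train: int | None = None  # default: 4 per seizure
    interictal_split: float = 0.5  # fraction of each record reserved for training anchors
    seed: int = 0


def _preictal_features(
    seizure_records: list[tuple[RRSeries, float]], config: ProtocolConfig
) -> np.ndarray:
    """One Λ per seizure, anchored at (just before) the onset."""
    vectors = []
    for rr, onset in seizure_records:
        anchor = min(float(onset), float(rr.beat_times[-1]))
        matrix = build_prediction_matrix(rr, anchor, config.windows)
        vectors.append(eigen_feature(covariance(matrix), anchor).vector)
    return np.array(vectors)


def _interictal_training_features(
    records: list[RRSeries], count: int, config: ProtocolConfig
) -> np.ndarray:
    """Λ vectors at seeded random anchors drawn from seizure-free records.

    Anchors are restricted to the first ``interictal_split`` fraction of
    each record; the remainder is held out for FP-rate testing.
    """
    rng = np.random.default_rng(config.seed)
    pool = []  # (record, anchor)
    for rec_idx, rr in enumerate(records):
        t = rr.beat_times[0] + config.windows.history_s
        t_stop = rr.beat_times[0] + config.interictal_split * rr.duration
        while t <= t_stop + 1e-9:
            pool.append((rec_idx, t))
            t += config.windows.step_s
    if len(pool) < count:
        raise ParameterError(
            f"interictal records provide only {len(pool)} candidate anchors, "
            f"{count} requested"
        )
    chosen = rng.choice(len(pool), size=count, replace=False)
    vectors = []
    for k in sorted(chosen):
        rec_idx, anchor = pool[k]
        matrix = build_prediction_matrix(records[rec_idx], anchor, config.windows)
        vectors.append(eigen_feature(covariance(matrix), anchor).vector)
    return np.array(vectors)


def _stream_vectors(
    rr: RRSeries, windows: WindowConfig
) -> tuple[np.ndarray, np.ndarray]:
    feats = list(stream_features(rr, windows))
    return (
        np.array([f.anchor_time for f in feats]),
        np.array([f.vector for f in feats]),
    )


def loocv_protocol(
    seizure_records: list[tuple[RRSeries, float]],
    interictal_records: list[RRSeries],
    config: ProtocolConfig | None = None,
) -> EvaluationReport:
    """Leave-one-seizure-out detection protocol.

    ``seizure_records`` holds ``(rr, onset_s)`` pairs whose RR data cover
    the onset with enough causal history; ``interictal_records`` are
    verified seizure-free.  Interictal training samples are drawn from the
    first ``interictal_split`` fraction of each seizure-free record; FP/h
    is measured on the strictly later, non-overlapping remainder
    (mirroring the separate train/test interictal periods of a clinical
    protocol).  Hyperparameters are fixed in ``config`` or chosen once by
    grouped-LOOCV grid search over the full training set.
    """
    config = config or ProtocolConfig()
    n_seizures = len(seizure_records)
    if n_seizures < 3:
        raise ParameterError("protocol needs at least 3 seizures")
    if len(interictal_records) < 2:
        raise ParameterError("protocol needs at least 2 interictal segments")

    preictal = _preictal_features(seizure_records, config)
    n_ii = config.n_interictal_train or 4 * n_seizures
    interictal = _interictal_training_features(interictal_records, n_ii, config)

    features = np.vstack([preictal, interictal])
    labels = np.array(
        [clf.PREICTAL] * n_seizures + [clf.INTERICTAL] * n_ii, dtype=object
    )
    provenance = np.array(
        [f"seizure-{i}" for i in range(n_seizures)]
        + [f"interictal-{j}" for j in range(n_ii)],
        dtype=object,
    )
    full_set = clf.TrainingSet(features, labels, provenance)

    if config.c is not None and config.gamma is not None:
        best_c, best_gamma, cv_acc = config.c, config.gamma, None
    else:
        best_c, best_gamma, cv_acc = clf.grid_search_loocv(
            full_set, config.c_grid, config.gamma_grid
        )

    # held-out interictal streams are model-independent: compute once.
    # only anchors whose full causal history lies after the training split
    # are scored; the monitored span defines the FP denominator.
    ii_streams = []
    ii_durations = []
    for rr in interictal_records:
        split_t = rr.beat_times[0] + config.interictal_split * rr.duration
        first_anchor = split_t + config.windows.history_s
        anchors, vectors = _stream_vectors(rr, config.windows)
        keep = anchors >= first_anchor - 1e-9
        if not np.any(keep):
            continue
        ii_streams.append((anchors[keep], vectors[keep]))
        ii_durations.append((rr.beat_times[-1] - first_anchor) / 3600.0)

    per_seizure = []
    seizure_warnings = []
    fp_series: list[WarningSeries] = []
    for i, (rr, onset) in enumerate(seizure_records):
        mask = np.ones(len(features), dtype=bool)
        mask[i] = False
        fold = clf.TrainingSet(features[mask], labels[mask], provenance[mask])
        model = clf.train(fold, best_c, best_gamma)

        ws = detect_stream(model, rr, config.windows)
        seizure_warnings.append(ws)
        hit = bool(
            np.any((ws.times >= onset - config.horizon_s) & (ws.times < onset))
        )
        per_seizure.append(
            {
                "seizure": i,
                "onset_s": float(onset),
                "detected": hit,
                "n_warnings": int(ws.times.size),
                "first_warning_in_horizon_s": float(
                    ws.times[
                        (ws.times >= onset - config.horizon_s) & (ws.times < onset)
                    ][0]
                )
                if hit
                else None,
            }
        )
        for (anchors, vectors), dur in zip(ii_streams, ii_durations):
            pred, _ = clf.predict_many(model, vectors)
            fp_series.append(
                warnings_from_outputs(anchors, pred == clf.PREICTAL, dur)
            )

    sens, detected, total = sensitivity(
        seizure_warnings, [onset for _, onset in seizure_records], config.horizon_s
    )
    fph = fp_rate(fp_series) if fp_series else 0.0
    return EvaluationReport(
        sensitivity=sens,
        detected=detected,
        total_seizures=total,
        fp_per_hour=fph,
        horizon_s=config.horizon_s,
        per_seizure=per_seizure,
        cv_accuracy=cv_acc,
        c=best_c,
        gamma=best_gamma,
    )
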