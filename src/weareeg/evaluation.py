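"""Model evaluation: time-slice cross-validation, event-level seizure
scoring, window-level workload scoring, macro-averaging, and the
recursive-feature-elimination harness.

Undefined metrics (for example sensitivity with no reference events)
propagate as ``None`` ("not applicable") and are excluded from
macro-averages — they are never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import EventList, Recording
from .detection import AlarmEvents


# ---------------------------------------------------------------------------
# Event-level seizure scoring


@dataclass(frozen=True)
class EventScore:
    """Event-level detection score: Sens = Tp/(Tp+Fn), Prec = Tp/(Tp+Fp),
    F1 = 2·Prec·Sens/(Prec+Sens), FAR = Fp·24/total_time_h (alarms/day)."""

    sens: float | None
    prec: float | None
    f1: float | None
    far_per_day: float | None
    tp: int = 0
    fp: int = 0
    fn: int = 0


def score_events(ref: EventList, hyp: AlarmEvents | EventList,
                 total_time_h: float | None = None) -> EventScore:
    """Score detected events against reference events by any-overlap
    matching: a reference event overlapped by >=1 alarm is one Tp (else
    one Fn); each alarm overlapping no reference event is one Fp.

    With no reference events, sensitivity (and F1) are not applicable
    and returned as ``None``. FAR needs ``total_time_h > 0``.
    """
    alarms = hyp.events if isinstance(hyp, AlarmEvents) else hyp
    tp = fn = 0
    for r in ref:
        if any(r.overlaps(a) for a in alarms):
            tp += 1
        else:
            fn += 1
    fp = sum(1 for a in alarms if not any(a.overlaps(r) for r in ref))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    if sens is None or prec is None or (sens + prec) == 0:
        f1 = None if (sens is None or prec is None) else 0.0
    else:
        f1 = 2 * prec * sens / (prec + sens)
    far = None
    if total_time_h is not None:
        if total_time_h <= 0:
            raise ValueError(f"total_time_h must be positive, got {total_time_h}")
        far = fp * 24.0 / total_time_h
    return EventScore(sens, prec, f1, far, tp, fp, fn)


def f1_score(sens: float, prec: float) -> float:
    """Harmonic mean of sensitivity and precision."""
    if sens + prec == 0:
        return 0.0
    return 2 * prec * sens / (prec + sens)


def aggregate_subjects(per_subject: Sequence[EventScore]) -> EventScore:
    """Macro-average: unweighted arithmetic mean of each metric across
    subjects, skipping not-applicable (None) entries per metric."""
    if not per_subject:
        raise ValueError("need at least one subject")

    def mean_of(attr: str) -> float | None:
        vals = [getattr(s, attr) for s in per_subject
                if getattr(s, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return EventScore(
        mean_of("sens"), mean_of("prec"), mean_of("f1"), mean_of("far_per_day"),
        tp=sum(s.tp for s in per_subject),
        fp=sum(s.fp for s in per_subject),
        fn=sum(s.fn for s in per_subject),
    )


# ---------------------------------------------------------------------------
# Window-level workload scoring


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    total_time_h: float | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class CWMScore:
    """Balanced-data scores in percent. ``gmean`` is the geometric mean of
    sensitivity and *specificity*: the score formula sometimes circulates
    with precision in place of specificity, but the specificity reading is
    the one consistent with published value tables (e.g. Sens 82.9 %,
    Spec 66.1 % -> Gmean 74.0 %), so that is what this package computes."""

    acc: float | None
    spec: float | None
    sens: float | None
    gmean: float | None


def gmean_percent(sens_pct: float, spec_pct: float) -> float:
    """Geometric mean of sensitivity and specificity, all in percent."""
    return math.sqrt(sens_pct * spec_pct)


def score_cwm(counts: ConfusionCounts) -> CWMScore:
    """Accuracy, specificity, sensitivity and Gmean (percent) from
    window-level confusion counts. Zero denominators yield None."""
    total = counts.tp + counts.tn + counts.fp + counts.fn
    acc = 100.0 * (counts.tp + counts.tn) / total if total else None
    spec = (100.0 * counts.tn / (counts.tn + counts.fp)
            if (counts.tn + counts.fp) else None)
    sens = (100.0 * counts.tp / (counts.tp + counts.fn)
            if (counts.tp + counts.fn) else None)
    gmean = gmean_percent(sens, spec) if (sens is not None and spec is not None) else None
    return CWMScore(acc, spec, sens, gmean)


# ---------------------------------------------------------------------------
# Time-slice cross-validation


@dataclass(frozen=True)
class Fold:
    train_span: tuple[float, float]  # [start, end) seconds on the subject timeline
    test_span: tuple[float, float]

    def __post_init__(self) -> None:
        if self.test_span[0] < self.train_span[1]:
            raise ValueError("test span must start at or after the train span ends")


@dataclass
class TSCVPlan:
    folds: list[Fold]
    record_offsets_s: list[float]
    skipped_reason: str | None = None

    def __bool__(self) -> bool:
        return bool(self.folds)


def subject_timeline(records: Sequence[Recording]
                     ) -> tuple[list[float], EventList, float]:
    """Concatenate records into one subject timeline: per-record start
    offsets, all events shifted onto the timeline, total duration (s)."""
    offsets: list[float] = []
    events = []
    t = 0.0
    for rec in records:
        offsets.append(t)
        for e in rec.events:
            events.append(type(e)(e.onset_s + t, e.offset_s + t, e.label))
        t += rec.duration_s
    return offsets, EventList(events), t


def tscv_split(records: Sequence[Recording], min_train_h: float = 5.0,
               min_train_seizures: int = 1,
               slice_h: float | None = None) -> TSCVPlan:
    """Plan ordered causal train/test slices over one subject's timeline.

    Candidate boundaries are record ends (the natural segmentation of a
    multi-file corpus) or, when ``slice_h`` is given, fixed slices of
    that many hours. The warm-up boundary is the first candidate with
    >= ``min_train_h`` hours of data and >= ``min_train_seizures``
    seizure events before it; fold k then trains on everything before
    boundary k and tests on the next slice. Test spans tile everything
    after the warm-up exactly once.

    A subject whose data cannot satisfy the warm-up is returned as an
    empty plan with a ``skipped_reason``.
    """
    offsets, events, total_s = subject_timeline(records)
    if slice_h is not None:
        step = slice_h * 3600.0
        boundaries = list(np.arange(step, total_s + 1e-9, step))
        if not boundaries or boundaries[-1] < total_s - 1e-6:
            boundaries.append(total_s)
    else:
        boundaries = [offsets[i] + records[i].duration_s
                      for i in range(len(records))]
    seizures = [e for e in events if e.label == "seizure"]
    min_train_s = min_train_h * 3600.0
    warmup = None
    for b in boundaries:
        n_sz = sum(1 for e in seizures if e.offset_s <= b)
        if b >= min_train_s and n_sz >= min_train_seizures:
            warmup = b
            break
    if warmup is None:
        if total_s < min_train_s:
            reason = (f"insufficient warm-up: {total_s/3600:.2f} h of data "
                      f"< required {min_train_h} h")
        else:
            reason = ("insufficient warm-up: no prefix with "
                      f"{min_train_seizures} seizure(s) and {min_train_h} h")
        return TSCVPlan([], offsets, skipped_reason=reason)
    test_bounds = [warmup] + [b for b in boundaries if b > warmup + 1e-9]
    if test_bounds[-1] < total_s - 1e-6:
        test_bounds.append(total_s)
    folds = [Fold((0.0, test_bounds[i]), (test_bounds[i], test_bounds[i + 1]))
             for i in range(len(test_bounds) - 1)]
    return TSCVPlan(folds, offsets)


# ---------------------------------------------------------------------------
# Recursive feature elimination


def _gmean_scorer(estimator, X, y) -> float:
    from sklearn.metrics import confusion_matrix

    pred = estimator.predict(X)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return math.sqrt(sens * spec)


def rfecv_select(X: np.ndarray, labels: Sequence[int], folds: int = 30,
                 n_trees: int = 25, seed: int = 0,
                 target_size: int | None = None) -> np.ndarray:
    """Recursive feature elimination, ranked by forest importance.

    Drops the weakest feature per iteration. With ``target_size`` the
    elimination stops at that many features; otherwise the subset
    maximizing cross-validated Gmean over ``folds`` stratified folds is
    selected. Returns the selected feature indices (sorted).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.feature_selection import RFE, RFECV
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if folds > len(y):
        raise ValueError(f"{folds} folds exceed {len(y)} samples")
    est = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 n_jobs=1)
    if target_size is not None:
        sel = RFE(est, n_features_to_select=target_size, step=1).fit(X, y)
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        sel = RFECV(est, step=1, cv=cv, scoring=_gmean_scorer,
                    min_features_to_select=1, n_jobs=1).fit(X, y)
    return np.flatnonzero(sel.support_)
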