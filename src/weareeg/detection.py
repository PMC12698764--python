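"""Random-Forest window inference, causal posterior smoothing, and
conversion of window decisions into alarm events.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core_io import Event, EventList
from .features import FeatureMatrix


@dataclass(frozen=True)
class RFConfig:
    """Forest configuration. 100 trees is the seizure-detection default;
    the workload configuration uses 200 trees (400 for a full-cap
    montage). ``max_per_class`` caps training windows per class by
    deterministic subsampling, which keeps hour-scale corpora tractable
    on one core."""

    n_trees: int = 100
    seed: int = 0
    class_weighting: str | None = "balanced"
    max_per_class: int | None = 5000


WORKLOAD_RF = RFConfig(n_trees=200)
FULLCAP_WORKLOAD_RF = RFConfig(n_trees=400)


@dataclass
class RFModel:
    clf: RandomForestClassifier
    manifest_hash: str
    config: RFConfig

    def predict_proba_ictal(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(X)
        pos = list(self.clf.classes_).index(1)
        return proba[:, pos]


def _manifest_hash(manifest: list[dict]) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]


def train_rf(features: FeatureMatrix | np.ndarray, labels: Sequence[int],
             config: RFConfig = RFConfig()) -> RFModel:
    """Fit a Random Forest on per-window features.

    Deterministic given ``config.seed``. Requires at least one window of
    each class; the model records the feature-manifest hash so it can
    refuse mismatched matrices downstream.
    """
    if isinstance(features, FeatureMatrix):
        X, _ = features.unmasked()
        manifest = features.manifest
    else:
        X = np.asarray(features, dtype=float)
        manifest = []
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    classes = np.unique(y)
    for cls in (0, 1):
        if cls not in classes:
            raise ValueError(f"training set lacks any window of class {cls}")
    if config.max_per_class is not None:
        rng = np.random.default_rng(config.seed)
        keep = np.zeros(len(y), dtype=bool)
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if len(idx) > config.max_per_class:
                idx = rng.choice(idx, size=config.max_per_class, replace=False)
            keep[idx] = True
        X, y = X[keep], y[keep]
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=config.seed,
        class_weight=config.class_weighting,
        n_jobs=1,
    )
    clf.fit(X, y)
    return RFModel(clf, _manifest_hash(manifest), config)


@dataclass(frozen=True)
class SmoothingConfig:
    """Causal log-odds accumulator: over a sliding window of ``horizon``
    past decisions, the posterior odds are the prior odds times the
    product of per-window likelihood ratios ``p/(1-p)``. ``horizon=1``
    with an uninformative prior is the identity."""

    prior: float = 0.5
    horizon: int = 8
    clip: float = 1e-6


def smooth_posteriors(p: np.ndarray, prior: float = 0.5, horizon: int = 8,
                      clip: float = 1e-6) -> np.ndarray:
    """Sequentially smooth per-window ictal probabilities.

    For window ``t`` the smoothed odds combine the prior with the
    likelihood ratios of windows ``t-horizon+1 .. t`` (causal: output at
    ``t`` never depends on later windows).
    """
    p = np.asarray(p, dtype=float)
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pc = np.clip(p, clip, 1 - clip)
    log_lr = np.log(pc) - np.log1p(-pc)
    prior_logodds = np.log(prior) - np.log1p(-prior)
    csum = np.concatenate([[0.0], np.cumsum(log_lr)])
    t = np.arange(len(p))
    lo = np.maximum(t - horizon + 1, 0)
    window_sum = csum[t + 1] - csum[lo]
    logodds = prior_logodds + window_sum
    smoothed = 1.0 / (1.0 + np.exp(-logodds))
    return np.clip(smoothed, clip, 1 - clip)


@dataclass
class WindowPosteriors:
    window_times: np.ndarray
    p_ictal: np.ndarray
    smoothed: np.ndarray
    threshold: float = 0.8
    win_s: float = 4.0

    def __post_init__(self) -> None:
        for arr in (self.p_ictal, self.smoothed):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("posteriors must lie in [0, 1]")


@dataclass
class AlarmEvents:
    events: EventList
    peak_posteriors: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


def build_events(posteriors: WindowPosteriors, threshold: float | None = None,
                 min_duration_s: float = 2.0, merge_gap_s: float = 30.0
                 ) -> AlarmEvents:
    """Turn supra-threshold posterior runs into alarm events.

    Maximal runs of ``smoothed >= threshold`` windows become candidates;
    candidates closer than ``merge_gap_s`` merge; candidates shorter than
    ``min_duration_s`` are dropped. Event onset is the first
    supra-threshold window's start time. Raising the threshold never
    increases the event count.
    """
    thr = posteriors.threshold if threshold is None else threshold
    t = posteriors.window_times
    s = posteriors.smoothed
    above = s >= thr
    runs: list[tuple[int, int]] = []  # inclusive window-index ranges
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # candidate intervals in seconds
    cands = [(t[i0], t[i1] + posteriors.win_s, float(s[i0:i1 + 1].max()))
             for i0, i1 in runs]
    # merge candidates separated by < merge_gap
    merged: list[list[float]] = []
    for on, off, pk in cands:
        if merged and on - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], off)
            merged[-1][2] = max(merged[-1][2], pk)
        else:
            merged.append([on, off, pk])
    kept = [(on, off, pk) for on, off, pk in merged
            if off - on >= min_duration_s]
    return AlarmEvents(
        EventList(Event(on, off, "alarm") for on, off, _ in kept),
        [pk for _, _, pk in kept],
    )
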