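"""Per-window, per-channel feature extraction.

The default registry holds exactly 56 features per channel, built from
the classic low-power EEG feature families: 8 time-domain statistics
(line length, mean amplitude, mean, variance, standard deviation, and
the three Hjorth parameters), 8 band powers (absolute + relative over
delta/theta/alpha/beta), 10 entropies (Shannon, Tsallis, Rényi, sample
and permutation entropy, two parameterizations each), and 30 wavelet
subband statistics (6 statistics x 5 subbands of a 4-level DWT). The
registry is an ordered, named manifest so the composition of any stored
feature matrix is auditable and configurable.

Every extractor has a batch implementation operating on an array of
windows at once, which is what makes hour-scale records tractable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy import signal

from .preprocess import Window, dwt_enhance

DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
}


# ---------------------------------------------------------------------------
# Time-domain statistics


@dataclass(frozen=True)
class TimeDomainFeatures:
    line_length: float
    mean_amplitude: float
    mean: float
    variance: float
    std: float
    hjorth_activity: float
    hjorth_mobility: float
    hjorth_complexity: float
    degenerate: bool = False


def time_domain(segment: np.ndarray) -> TimeDomainFeatures:
    """Time-domain statistics of one segment.

    Variance is the population (1/n) variance, matching the
    signal-power semantics of Hjorth activity. For a constant segment,
    mobility and complexity are returned as 0 with ``degenerate=True``.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("time-domain features need >= 3 samples")
    batch = _time_domain_batch(x[None, :])
    degenerate = bool(np.var(x) == 0)
    return TimeDomainFeatures(*(float(v[0]) for v in batch), degenerate)


def _time_domain_batch(x: np.ndarray) -> list[np.ndarray]:
    """x: (n, L) -> list of 8 arrays (n,)."""
    dx = np.diff(x, axis=1)
    ddx = np.diff(dx, axis=1)
    line_length = np.abs(dx).sum(axis=1)
    mean_amplitude = np.abs(x).mean(axis=1)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    std = np.sqrt(var)
    var_d = dx.var(axis=1)
    var_dd = ddx.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.where(var > 0, np.sqrt(var_d / np.where(var > 0, var, 1)), 0.0)
        mob_d = np.where(var_d > 0, np.sqrt(var_dd / np.where(var_d > 0, var_d, 1)), 0.0)
        complexity = np.where(mobility > 0, mob_d / np.where(mobility > 0, mobility, 1), 0.0)
    return [line_length, mean_amplitude, mean, var, std, var, mobility, complexity]


# ---------------------------------------------------------------------------
# Band powers


def band_powers(segment: np.ndarray, fs: float,
                bands: dict[str, tuple[float, float]] = DEFAULT_BANDS
                ) -> dict[str, float]:
    """Absolute and relative Welch band powers of one segment.

    Returns ``{"abs_<band>": ..., "rel_<band>": ...}``. Relative powers
    sum to 1 over the defined bands; for an all-zero segment the
    relative powers are undefined and returned as NaN.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < fs:
        raise ValueError("band powers need >= 1 s of data")
    for name, (lo, hi) in bands.items():
        if hi > fs / 2:
            raise ValueError(f"band {name} [{lo},{hi}) exceeds Nyquist {fs/2}")
    absed, reled = _band_power_batch(x[None, :], fs, bands, nan_undefined=True)
    out = {}
    for i, name in enumerate(bands):
        out[f"abs_{name}"] = float(absed[0, i])
    for i, name in enumerate(bands):
        out[f"rel_{name}"] = float(reled[0, i])
    return out


def _band_power_batch(x: np.ndarray, fs: float,
                      bands: dict[str, tuple[float, float]],
                      nan_undefined: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
    nper = min(x.shape[1], int(round(2 * fs)))
    f, psd = signal.welch(x, fs=fs, nperseg=nper, axis=1)
    df = f[1] - f[0]
    absed = np.empty((x.shape[0], len(bands)))
    for i, (lo, hi) in enumerate(bands.values()):
        sel = (f >= lo) & (f < hi)
        absed[:, i] = psd[:, sel].sum(axis=1) * df
    total = absed.sum(axis=1, keepdims=True)
    if nan_undefined:
        with np.errstate(invalid="ignore", divide="ignore"):
            reled = np.where(total > 0, absed / total, np.nan)
    else:
        reled = np.divide(absed, total, out=np.zeros_like(absed),
                          where=total > 0)
    return absed, reled


# ---------------------------------------------------------------------------
# Entropies


def _histogram_probs(x: np.ndarray, bins: int) -> np.ndarray:
    """Per-row amplitude-histogram probabilities over mean ± 3·std.

    x: (n, L) -> (n, bins). Samples beyond the support clip into the edge
    bins; constant rows collapse into one bin.
    """
    n, L = x.shape
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    lo = mu - 3 * sd
    span = np.where(sd > 0, 6 * sd, 1.0)
    idx = np.floor((x - lo) / span * bins).astype(np.int64)
    np.clip(idx, 0, bins - 1, out=idx)
    codes = idx + bins * np.arange(n)[:, None]
    counts = np.bincount(codes.ravel(), minlength=n * bins).reshape(n, bins)
    return counts / L


def _shannon_from_p(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def _tsallis_from_p(p: np.ndarray, q: float) -> np.ndarray:
    if abs(q - 1.0) < 1e-12:
        return _shannon_from_p(p)
    return (1.0 - (p**q).sum(axis=1)) / (q - 1.0)


def _renyi_from_p(p: np.ndarray, alpha: float) -> np.ndarray:
    if abs(alpha - 1.0) < 1e-12:
        return _shannon_from_p(p)
    return np.log((p**alpha).sum(axis=1)) / (1.0 - alpha)


@njit(cache=True)
def _sampen_one(x: np.ndarray, m: int, r: float) -> float:
    n = x.shape[0]
    nt = n - m  # templates of length m whose (m+1)-th sample exists
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        return np.inf
    return -math.log(a / b)


@njit(cache=True)
def _sampen_batch(x: np.ndarray, m: int, r_factor: float) -> np.ndarray:
    n = x.shape[0]
    out = np.empty(n)
    for i in range(n):
        row = x[i]
        sd = row.std()
        if sd == 0.0:
            out[i] = 0.0
        else:
            out[i] = _sampen_one(row, m, r_factor * sd)
    return out


def sample_entropy(segment: np.ndarray, m: int = 2, r: float | None = None
                   ) -> float:
    """Sample entropy ``-ln(A/B)`` with Chebyshev template matching.

    ``r`` defaults to ``0.2 * std(segment)``. Zero matches at length
    ``m+1`` return ``inf`` (no regularity evidence).
    """
    x = np.asarray(segment, dtype=float)
    if r is None:
        r = 0.2 * float(x.std())
    if x.std() == 0:
        return 0.0
    return float(_sampen_one(x, m, r))


def _perm_codes(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    n, L = x.shape
    npat = L - (order - 1) * delay
    emb = np.stack([x[:, k * delay: k * delay + npat] for k in range(order)],
                   axis=2)  # (n, npat, order)
    ranks = np.argsort(emb, axis=2, kind="stable")
    weights = order ** np.arange(order)
    return (ranks * weights).sum(axis=2)  # (n, npat)


def _perm_entropy_batch(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    codes = _perm_codes(x, order, delay)
    n, npat = codes.shape
    out = np.empty(n)
    norm = math.log(math.factorial(order))
    for i in range(n):
        counts = np.bincount(codes[i])
        p = counts[counts > 0] / npat
        out[i] = -(p * np.log(p)).sum() / norm
    return out


def permutation_entropy(segment: np.ndarray, order: int = 3, delay: int = 1
                        ) -> float:
    """Permutation entropy of ordinal patterns, normalized to [0, 1] by
    ``ln(order!)``. A strictly monotone segment has a single pattern and
    entropy 0."""
    x = np.asarray(segment, dtype=float)
    return float(_perm_entropy_batch(x[None, :], order, delay)[0])


def shannon_entropy(segment: np.ndarray, bins: int = 10) -> float:
    """Shannon entropy (natural log) of the amplitude histogram."""
    return float(_shannon_from_p(
        _histogram_probs(np.asarray(segment, float)[None, :], bins))[0])


def tsallis_entropy(segment: np.ndarray, q: float = 2.0, bins: int = 10) -> float:
    """Tsallis entropy ``(1 - sum p^q)/(q-1)``; ``q -> 1`` recovers Shannon."""
    return float(_tsallis_from_p(
        _histogram_probs(np.asarray(segment, float)[None, :], bins), q)[0])


def renyi_entropy(segment: np.ndarray, alpha: float = 2.0, bins: int = 10) -> float:
    """Rényi entropy ``ln(sum p^alpha)/(1-alpha)``; ``alpha -> 1`` recovers
    Shannon."""
    return float(_renyi_from_p(
        _histogram_probs(np.asarray(segment, float)[None, :], bins), alpha)[0])


def entropies(segment: np.ndarray, bins: int = 10, q: float = 2.0,
              alpha: float = 2.0, m: int = 2, r: float | None = None,
              order: int = 3, delay: int = 1) -> dict[str, float]:
    """The five entropy families on one segment with one parameterization
    each."""
    return {
        "shannon": shannon_entropy(segment, bins),
        "tsallis": tsallis_entropy(segment, q, bins),
        "renyi": renyi_entropy(segment, alpha, bins),
        "sample_entropy": sample_entropy(segment, m, r),
        "permutation_entropy": permutation_entropy(segment, order, delay),
    }


# ---------------------------------------------------------------------------
# Wavelet subband statistics

_DWT_STATS = ("mean", "std", "energy", "mean_abs", "line_length", "max_abs")


def _dwt_stats_batch(x: np.ndarray, wavelet: str = "db4", levels: int = 4
                     ) -> np.ndarray:
    """x: (n, L) -> (n, 6 * (levels + 1)) subband statistics, ordered
    approximation first, then details coarse-to-fine, 6 statistics each."""
    coeffs = dwt_enhance(x, wavelet=wavelet, levels=levels)
    cols = []
    for c in coeffs:
        cols.extend([
            c.mean(axis=1),
            c.std(axis=1),
            (c**2).sum(axis=1),
            np.abs(c).mean(axis=1),
            np.abs(np.diff(c, axis=1)).sum(axis=1),
            np.abs(c).max(axis=1),
        ])
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class FeatureDef:
    name: str
    batch_fn: Callable[[np.ndarray, float], np.ndarray]  # (n, L), fs -> (n,)
    params: dict = field(default_factory=dict)


class FeatureRegistry:
    """Ordered, named feature manifest. Extraction preserves this order,
    and the manifest (names + parameters) is written alongside every
    feature matrix."""

    def __init__(self, defs: Sequence[FeatureDef]):
        names = [d.name for d in defs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.defs = list(defs)

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def manifest(self) -> list[dict]:
        return [{"name": d.name, "params": d.params} for d in self.defs]


def default_registry(bins: int = 10) -> FeatureRegistry:
    """The 56-entry default registry (see module docstring)."""
    td_names = ["line_length", "mean_amplitude", "mean", "variance", "std",
                "hjorth_activity", "hjorth_mobility", "hjorth_complexity"]
    defs: list[FeatureDef] = []
    for i, nm in enumerate(td_names):
        defs.append(FeatureDef(nm, _make_td(i)))
    for i, band in enumerate(DEFAULT_BANDS):
        defs.append(FeatureDef(f"abs_power_{band}", _make_bp(i, absolute=True),
                               {"band": DEFAULT_BANDS[band]}))
    for i, band in enumerate(DEFAULT_BANDS):
        defs.append(FeatureDef(f"rel_power_{band}", _make_bp(i, absolute=False),
                               {"band": DEFAULT_BANDS[band]}))
    defs += [
        FeatureDef("shannon_b10", _make_hist("shannon", bins=10), {"bins": 10}),
        FeatureDef("shannon_b20", _make_hist("shannon", bins=20), {"bins": 20}),
        FeatureDef("tsallis_q2", _make_hist("tsallis", bins=10, q=2.0),
                   {"bins": 10, "q": 2.0}),
        FeatureDef("tsallis_q3", _make_hist("tsallis", bins=10, q=3.0),
                   {"bins": 10, "q": 3.0}),
        FeatureDef("renyi_a2", _make_hist("renyi", bins=10, alpha=2.0),
                   {"bins": 10, "alpha": 2.0}),
        FeatureDef("renyi_a05", _make_hist("renyi", bins=10, alpha=0.5),
                   {"bins": 10, "alpha": 0.5}),
        FeatureDef("sampen_m2", lambda x, fs: _finite(_sampen_batch(
            np.ascontiguousarray(x), 2, 0.2)), {"m": 2, "r": "0.2*std"}),
        FeatureDef("sampen_m3", lambda x, fs: _finite(_sampen_batch(
            np.ascontiguousarray(x), 3, 0.2)), {"m": 3, "r": "0.2*std"}),
        FeatureDef("perm_entropy_o3", lambda x, fs: _perm_entropy_batch(x, 3, 1),
                   {"order": 3, "delay": 1}),
        FeatureDef("perm_entropy_o5", lambda x, fs: _perm_entropy_batch(x, 5, 1),
                   {"order": 5, "delay": 1}),
    ]
    subbands = ["a4", "d4", "d3", "d2", "d1"]
    for bi, sb in enumerate(subbands):
        for si, stat in enumerate(_DWT_STATS):
            defs.append(FeatureDef(f"dwt_{sb}_{stat}", _make_dwt(bi, si),
                                   {"wavelet": "db4", "levels": 4}))
    reg = FeatureRegistry(defs)
    assert len(reg) == 56
    return reg


def _finite(v: np.ndarray) -> np.ndarray:
    """Replace the +inf no-match sentinel with a large finite value so the
    matrix stays numeric (the sentinel meaning is 'maximally irregular')."""
    out = np.asarray(v, dtype=float).copy()
    out[~np.isfinite(out)] = 50.0
    return out


def _make_td(i: int):
    return lambda x, fs: _time_domain_batch(x)[i]


def _make_bp(i: int, absolute: bool):
    def run(x, fs):
        absed, reled = _band_power_batch(x, fs, DEFAULT_BANDS)
        return absed[:, i] if absolute else reled[:, i]
    return run


def _make_hist(kind: str, bins: int, q: float = 2.0, alpha: float = 2.0):
    def run(x, fs):
        p = _histogram_probs(x, bins)
        if kind == "shannon":
            return _shannon_from_p(p)
        if kind == "tsallis":
            return _tsallis_from_p(p, q)
        return _renyi_from_p(p, alpha)
    return run


def _make_dwt(band_idx: int, stat_idx: int):
    return lambda x, fs: _dwt_stats_batch(x)[:, band_idx * len(_DWT_STATS)
                                              + stat_idx]


# Batch-group optimization: these groups share one expensive computation,
# so extract() evaluates each group once per channel instead of per column.
_GROUPS = {
    "td": (lambda x, fs: np.column_stack(_time_domain_batch(x)),
           ["line_length", "mean_amplitude", "mean", "variance", "std",
            "hjorth_activity", "hjorth_mobility", "hjorth_complexity"]),
    "bp": (lambda x, fs: np.column_stack(_band_power_batch(x, fs, DEFAULT_BANDS)),
           [f"abs_power_{b}" for b in DEFAULT_BANDS]
           + [f"rel_power_{b}" for b in DEFAULT_BANDS]),
    "dwt": (lambda x, fs: _dwt_stats_batch(x),
            [f"dwt_{sb}_{stat}" for sb in ("a4", "d4", "d3", "d2", "d1")
             for stat in _DWT_STATS]),
}


# ---------------------------------------------------------------------------
# FeatureMatrix


@dataclass
class FeatureMatrix:
    """Window x (channel x feature) value grid.

    Rows of masked windows hold NaN; unmasked rows are complete. Column
    ``c * n_features + f`` is feature ``f`` of channel ``c``; column names
    are ``"<channel>|<feature>"``.
    """

    values: np.ndarray
    feature_names: list[str]
    channel_labels: list[str]
    window_times: np.ndarray
    mask: np.ndarray
    manifest: list[dict] = field(default_factory=list)

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}|{nm}" for ch in self.channel_labels
                for nm in self.feature_names]

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.mask
        return self.values[keep], self.window_times[keep]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "window_time_s", self.window_times)
        df.insert(1, "masked", self.mask.astype(int))
        df.to_csv(path, index=False)
        Path(str(path) + ".manifest.json").write_text(
            json.dumps(self.manifest, indent=1))


def extract(windows: list[Window], fs: float, channel_labels: Sequence[str],
            registry: FeatureRegistry | None = None,
            mask: np.ndarray | None = None,
            chunk_size: int = 2048) -> FeatureMatrix:
    """Extract the registry's features for every channel of every window.

    Masked windows are skipped (their rows are NaN and their indices
    retained). A failing extractor flags its windows NaN and the run
    continues. Windows are processed in chunks of ``chunk_size`` so that
    heavily overlapping window lists (which are views into the signal)
    are never materialized as one giant array.
    """
    if not windows:
        raise ValueError("no windows to extract features from")
    registry = registry or default_registry()
    n = len(windows)
    nch = windows[0].data.shape[0]
    times = np.array([w.start_s for w in windows])
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    keep_idx = np.flatnonzero(~mask)
    nf = len(registry)
    values = np.full((n, nch * nf), np.nan)

    # map registry names to fast group slots where available
    group_cols: dict[str, dict[str, int]] = {
        g: {nm: i for i, nm in enumerate(names)} for g, (_, names) in _GROUPS.items()
    }

    for lo in range(0, len(keep_idx), chunk_size):
        idx = keep_idx[lo:lo + chunk_size]
        data = np.stack([windows[i].data for i in idx])  # (chunk, ch, L)
        for c in range(nch):
            x = np.ascontiguousarray(data[:, c, :])
            group_out: dict[str, np.ndarray] = {}
            for g, (fn, _) in _GROUPS.items():
                if any(d.name in group_cols[g] for d in registry.defs):
                    group_out[g] = fn(x, fs)
            for fi, d in enumerate(registry.defs):
                col = c * nf + fi
                try:
                    hit = next((g for g in _GROUPS
                                if d.name in group_cols[g]), None)
                    if hit is not None:
                        vals = group_out[hit][:, group_cols[hit][d.name]]
                    else:
                        vals = d.batch_fn(x, fs)
                    values[idx, col] = vals
                except Exception:  # extractor failure: flag and continue
                    values[idx, col] = np.nan
    return FeatureMatrix(values, registry.names, list(channel_labels), times,
                         mask, registry.manifest())
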