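"""Dual-device agreement analysis: DTW-aligned Pearson correlation,
Welch periodogram comparison, and Bland–Altman analysis of spectral
differences.

Two devices observing the same physiology at different sampling rates
drift apart sample-to-sample even after nominal resampling. The
alignment here is deliberately conservative: band-limited resampling to
a common rate first, then dynamic time warping restricted to a narrow
Sakoe–Chiba band (default 0.25 s) for the residual timing error, with
warped duplicates averaged per reference index so each reference sample
pairs with exactly one aligned value. An unconstrained DTW would inflate
the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numba import njit
from scipy import signal
from scipy.stats import pearsonr

from .core_io import Recording


@njit(cache=True)
def _dtw_band_path(a: np.ndarray, b: np.ndarray, band: int):
    """Banded DTW (symmetric step pattern, squared distance).

    Returns the warping path as two index arrays (reference index into
    ``a``, query index into ``b``), computed on a Sakoe–Chiba band of
    half-width ``band`` samples around the diagonal.
    """
    n = a.shape[0]
    m = b.shape[0]
    width = 2 * band + 1
    INF = 1e300
    # cost[i, k] = cumulative cost at (i, j) with j = diag(i) + k - band
    cost = np.full((n, width), INF)
    slope = m / n

    for i in range(n):
        jc = int(i * slope)
        for k in range(width):
            j = jc + k - band
            if j < 0 or j >= m:
                continue
            d = a[i] - b[j]
            d = d * d
            if i == 0 and j == 0:
                cost[i, k] = d
                continue
            best = INF
            # predecessors: (i-1, j), (i, j-1), (i-1, j-1)
            if i > 0:
                jc_prev = int((i - 1) * slope)
                kk = j - jc_prev + band
                if 0 <= kk < width and cost[i - 1, kk] < best:
                    best = cost[i - 1, kk]
                kk = j - 1 - jc_prev + band
                if j > 0 and 0 <= kk < width and cost[i - 1, kk] < best:
                    best = cost[i - 1, kk]
            if j > 0:
                kk = j - 1 - jc + band
                if 0 <= kk < width and cost[i, kk] < best:
                    best = cost[i, kk]
            if best < INF:
                cost[i, k] = d + best

    # backtrack from (n-1, m-1)
    max_len = n + m
    pi = np.empty(max_len, dtype=np.int64)
    pj = np.empty(max_len, dtype=np.int64)
    i = n - 1
    j = m - 1
    idx = 0
    while True:
        pi[idx] = i
        pj[idx] = j
        idx += 1
        if i == 0 and j == 0:
            break
        best = INF
        bi, bj = i, j
        if i > 0 and j > 0:
            jc_prev = int((i - 1) * slope)
            kk = j - 1 - jc_prev + band
            if 0 <= kk < 2 * band + 1 and cost[i - 1, kk] < best:
                best = cost[i - 1, kk]
                bi, bj = i - 1, j - 1
        if i > 0:
            jc_prev = int((i - 1) * slope)
            kk = j - jc_prev + band
            if 0 <= kk < 2 * band + 1 and cost[i - 1, kk] < best:
                best = cost[i - 1, kk]
                bi, bj = i - 1, j
        if j > 0:
            jc = int(i * slope)
            kk = j - 1 - jc + band
            if 0 <= kk < 2 * band + 1 and cost[i, kk] < best:
                best = cost[i, kk]
                bi, bj = i, j - 1
        if bi == i and bj == j:  # stuck (shouldn't happen inside the band)
            break
        i, j = bi, bj
    jc_end = int((n - 1) * slope)
    end_cost = cost[n - 1, (m - 1) - jc_end + band]
    return pi[:idx][::-1], pj[:idx][::-1], end_cost


def _resample_to(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    if fs_from == fs_to:
        return x
    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def align_and_correlate(a: Recording, b: Recording, window_s: float = 60.0,
                        channel: str | int = 0, band_s: float = 0.25,
                        start_s: float = 0.0) -> float:
    """DTW-aligned Pearson correlation between the same channel of two
    recordings over one analysis window.

    ``b`` is resampled to ``a``'s rate; both segments are z-scored; DTW
    restricted to a ``band_s`` Sakoe–Chiba band aligns them; warped
    ``b`` values are averaged per ``a`` index; Pearson r is computed on
    the aligned pair (using the raw, unstandardized amplitudes —
    z-scoring only steers the warping).
    """
    for name, rec in (("first", a), ("second", b)):
        if rec.duration_s < start_s + window_s:
            raise ValueError(
                f"{name} recording ({rec.duration_s:g} s) shorter than the "
                f"{window_s:g} s analysis window"
            )
    xa = a.samples[channel] if isinstance(channel, int) else a.channel(channel)
    xb = b.samples[channel] if isinstance(channel, int) else b.channel(channel)
    i0 = int(start_s * a.fs)
    xa = xa[i0:i0 + int(window_s * a.fs)]
    xb = _resample_to(xb, b.fs, a.fs)
    i0 = int(start_s * a.fs)
    xb = xb[i0:i0 + int(window_s * a.fs)]
    n = min(len(xa), len(xb))
    xa, xb = xa[:n], xb[:n]
    band = max(int(band_s * a.fs), 1)
    # polarity-aware alignment: a flipped electrode pair is anti-phase,
    # and warping z-scores against the wrong polarity would let DTW
    # shift by half-periods to fake a positive match. Align against the
    # polarity with the lower warping cost; correlate the raw values.
    za, zb = _zscore(xa), _zscore(xb)
    pi_pos, pj_pos, cost_pos = _dtw_band_path(za, zb, band)
    pi_neg, pj_neg, cost_neg = _dtw_band_path(za, -zb, band)
    pi, pj = (pi_pos, pj_pos) if cost_pos <= cost_neg else (pi_neg, pj_neg)
    # average warped b per a index
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, pi, xb[pj])
    np.add.at(counts, pi, 1.0)
    aligned_b = sums / np.maximum(counts, 1.0)
    r, _ = pearsonr(xa, aligned_b)
    return float(r)


@dataclass
class PSDPair:
    freqs: np.ndarray
    psd_a: np.ndarray
    psd_b: np.ndarray


def welch_psd(rec: Recording, epoch_s: float = 4.0,
              span_s: float | None = None, channel: str | int = 0,
              start_s: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Averaged periodogram over ``epoch_s`` epochs (Hann taper, 50%
    overlap) of one channel; frequency resolution is ``1/epoch_s`` Hz.
    The integral of the returned density recovers the segment variance
    within taper tolerance."""
    x = rec.samples[channel] if isinstance(channel, int) else rec.channel(channel)
    i0 = int(start_s * rec.fs)
    if span_s is not None:
        if rec.duration_s < start_s + span_s:
            raise ValueError(
                f"span of {span_s:g} s not available in a {rec.duration_s:g} s "
                "recording"
            )
        x = x[i0:i0 + int(span_s * rec.fs)]
    else:
        x = x[i0:]
    nper = int(round(epoch_s * rec.fs))
    if len(x) < nper:
        raise ValueError(
            f"need >= one {epoch_s:g} s epoch, have {len(x)/rec.fs:g} s"
        )
    f, psd = signal.welch(x, fs=rec.fs, window="hann", nperseg=nper,
                          noverlap=nper // 2, detrend="constant")
    return f, psd


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    fraction_inside: float
    n: int


def bland_altman(psd_a: np.ndarray, psd_b: np.ndarray,
                 freqs_a: np.ndarray | None = None,
                 freqs_b: np.ndarray | None = None,
                 log: bool = False) -> BlandAltman:
    """Bland–Altman agreement between two spectra on one frequency grid.

    Per-bin differences ``d = a - b``; limits of agreement are
    ``MD ± 1.96·SD``; the fraction of bins inside the limits is reported
    (≈0.95 for Gaussian differences). ``log=True`` compares log10 power.
    """
    a = np.asarray(psd_a, dtype=float)
    b = np.asarray(psd_b, dtype=float)
    if freqs_a is not None and freqs_b is not None:
        if len(freqs_a) != len(freqs_b) or not np.allclose(freqs_a, freqs_b):
            raise ValueError("PSD frequency grids do not match")
    if a.shape != b.shape:
        raise ValueError(f"PSD shapes differ: {a.shape} vs {b.shape}")
    if log:
        a, b = np.log10(a), np.log10(b)
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    lo, hi = md - 1.96 * sd, md + 1.96 * sd
    inside = float(np.mean((d >= lo) & (d <= hi))) if d.size else 0.0
    return BlandAltman(md, sd, lo, hi, inside, d.size)


@dataclass
class AgreementReport:
    pearson_r: float
    psd: PSDPair
    bland_altman: BlandAltman

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "bland_altman": {
                "mean_difference": self.bland_altman.mean_difference,
                "sd_difference": self.bland_altman.sd_difference,
                "limits": [self.bland_altman.lower_limit,
                           self.bland_altman.upper_limit],
                "fraction_inside": self.bland_altman.fraction_inside,
            },
            "psd_bins": len(self.psd.freqs),
        }


def compare_devices(a: Recording, b: Recording, window_s: float = 60.0,
                    epoch_s: float = 4.0, span_s: float | None = None,
                    channel: str | int = 0) -> AgreementReport:
    """Full agreement analysis of one shared channel: DTW-aligned
    correlation, per-device Welch spectra on a common grid, and
    Bland–Altman statistics of their difference."""
    r = align_and_correlate(a, b, window_s=window_s, channel=channel)
    # common grid: estimate b's PSD after resampling it to a's rate
    b_rs = b.copy_with(samples=_resample_to(b.samples, b.fs, a.fs), fs=a.fs)
    span = span_s
    if span is None:
        span = min(a.duration_s, b_rs.duration_s)
        span = epoch_s * int(span / epoch_s)
    fa, pa = welch_psd(a, epoch_s=epoch_s, span_s=span, channel=channel)
    fb, pb = welch_psd(b_rs, epoch_s=epoch_s, span_s=span, channel=channel)
    ba = bland_altman(pa, pb, fa, fb)
    return AgreementReport(r, PSDPair(fa, pa, pb), ba)
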