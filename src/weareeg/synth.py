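"""Seeded synthetic-EEG generators.

These emulate the signal classes the rest of the toolkit consumes without
any external data: 1/f background with band oscillations, eye-closure
alpha synchronization, rhythmic ictal discharges, blink/movement
artifacts, quantized front-end noise floors, and a second-device view of
the same physiology. Every generator is a pure function of its spec
(seed included): the same spec yields bit-identical output.

Amplitudes in specs are given in microvolts for convenience; generated
Recordings are in volts like everything else in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .core_io import AcquisitionSpec, Event, EventList, Recording

UV = 1e-6


@dataclass(frozen=True)
class SeizureSpec:
    onset_s: float
    duration_s: float
    discharge_hz: float = 4.0
    amplitude_uv: float = 100.0


@dataclass(frozen=True)
class SynthSpec:
    fs: float = 128.0
    duration_s: float = 60.0
    channel_labels: tuple[str, ...] = ("F7T7", "F8T8")
    # background: power-law spectrum exponent and per-band oscillation
    # amplitudes (µV) at representative band centres
    background_slope: float = 1.0
    background_rms_uv: float = 20.0
    oscillations_uv: tuple[tuple[float, float], ...] = ()  # (freq Hz, amp µV)
    # eye-closure alpha
    alpha_hz: float = 10.0
    alpha_uv: float = 20.0
    eye_closure_intervals: tuple[tuple[float, float], ...] = ()
    # seizures
    seizures: tuple[SeizureSpec, ...] = ()
    # artifacts
    blink_rate_per_min: float = 0.0
    blink_uv: float = 150.0
    # additive front-end noise
    noise_rms_uv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        amps = [self.background_rms_uv, self.alpha_uv, self.blink_uv,
                self.noise_rms_uv, *(s.amplitude_uv for s in self.seizures)]
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        for s in self.seizures:
            if s.onset_s < 0 or s.onset_s + s.duration_s > self.duration_s:
                raise ValueError(
                    f"seizure [{s.onset_s}, {s.onset_s + s.duration_s}) s "
                    f"falls outside the {self.duration_s} s record"
                )


def _n_samples(spec: SynthSpec) -> int:
    return int(round(spec.duration_s * spec.fs))


def _powerlaw_noise(rng: np.random.Generator, n: int, fs: float,
                    slope: float, rms: float) -> np.ndarray:
    """Gaussian noise shaped to a 1/f**slope amplitude spectrum, unit-free,
    scaled to the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-slope / 2.0)  # PSD ~ f^-slope  =>  amp ~ f^-slope/2
    shaping[0] = 0.0  # no DC
    # keep power-law shape only above 0.5 Hz to bound low-frequency energy
    lowcut = (f > 0) & (f < 0.5)
    shaping[lowcut] = shaping[f >= 0.5][0] if np.any(f >= 0.5) else 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def _background_channel(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    n = _n_samples(spec)
    x = _powerlaw_noise(rng, n, spec.fs, spec.background_slope,
                        spec.background_rms_uv)
    t = np.arange(n) / spec.fs
    for freq, amp in spec.oscillations_uv:
        x += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return x


def _quantize(x: np.ndarray, step_v: float) -> np.ndarray:
    if step_v <= 0:
        return x
    return np.round(x / step_v) * step_v


def gen_background(spec: SynthSpec) -> Recording:
    """Background EEG: 1/f**slope spectrum plus configured oscillations."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = _n_samples(spec)
    chans = np.empty((len(spec.channel_labels), n))
    for c in range(len(spec.channel_labels)):
        chans[c] = _background_channel(rng, spec)
        if spec.noise_rms_uv:
            chans[c] += rng.standard_normal(n) * spec.noise_rms_uv
    return Recording(chans * UV, spec.fs, list(spec.channel_labels),
                     montage="bipolar" if all(len(l) > 3 for l in spec.channel_labels)
                     else "referential")


def gen_alpha_session(spec: SynthSpec) -> Recording:
    """Eyes-open/closed session: alpha oscillation present only inside the
    configured eye-closure intervals, which are annotated as events."""
    spec.validate()
    if not 8.0 <= spec.alpha_hz <= 12.0:
        warnings.warn(
            f"alpha centre {spec.alpha_hz} Hz lies outside the alpha band [8, 12] Hz"
        )
    rec = gen_background(spec)
    n = rec.n_samples
    t = np.arange(n) / spec.fs
    gate = np.zeros(n)
    events = []
    for onset, offset in spec.eye_closure_intervals:
        i0, i1 = int(round(onset * spec.fs)), int(round(offset * spec.fs))
        gate[i0:i1] = 1.0
        events.append(Event(onset, offset, "eyes_closed"))
    # smooth the gate edges over ~0.25 s so onsets are not spectral clicks
    edge = max(int(0.25 * spec.fs), 1)
    gate = np.convolve(gate, np.ones(edge) / edge, mode="same")
    rng = np.random.default_rng(spec.seed + 1)
    alpha = spec.alpha_uv * np.sin(2 * np.pi * spec.alpha_hz * t
                                   + rng.uniform(0, 2 * np.pi))
    samples = rec.samples + (gate * alpha)[None, :] * UV
    return rec.copy_with(samples=samples, events=EventList(events))


def _seizure_waveform(rng: np.random.Generator, fs: float, sz: SeizureSpec
                      ) -> np.ndarray:
    """Amplitude-modulated rhythmic discharge with a mild downward
    frequency chirp plus a second harmonic — produces the line-length and
    low-band power contrast ictal EEG shows without claiming physiological
    realism."""
    n = int(round(sz.duration_s * fs))
    t = np.arange(n) / fs
    # chirp from discharge_hz down to 3/4 of it across the event
    f1 = 0.75 * sz.discharge_hz
    phase = 2 * np.pi * (sz.discharge_hz * t + (f1 - sz.discharge_hz)
                         * t**2 / (2 * sz.duration_s))
    wave = np.sin(phase + rng.uniform(0, 2 * np.pi))
    wave += 0.4 * np.sin(2 * phase)
    # amplitude ramps up over the first third, sustains, decays at the end
    ramp = np.minimum(1.0, t / max(sz.duration_s / 3.0, 1e-9))
    decay = np.minimum(1.0, (sz.duration_s - t) / max(sz.duration_s / 6.0, 1e-9))
    return sz.amplitude_uv * wave * ramp * decay


def _blink_train(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    """Low-frequency biphasic blink pulses at the configured rate."""
    n = _n_samples(spec)
    x = np.zeros(n)
    if spec.blink_rate_per_min <= 0 or spec.blink_uv <= 0:
        return x
    n_blinks = rng.poisson(spec.blink_rate_per_min * spec.duration_s / 60.0)
    width = 0.35  # seconds; energy below ~4 Hz
    wlen = int(width * spec.fs)
    tt = np.linspace(0, width, wlen)
    pulse = np.sin(2 * np.pi * tt / width) * np.exp(-((tt - width / 2) ** 2)
                                                    / (width / 4) ** 2)
    pulse *= spec.blink_uv / np.abs(pulse).max()
    for _ in range(n_blinks):
        i0 = rng.integers(0, max(n - wlen, 1))
        x[i0:i0 + wlen] += pulse[: n - i0]
    return x


def gen_seizure_record(spec: SynthSpec) -> Recording:
    """One record: background plus annotated ictal discharges on all
    channels, plus blinks on the first (frontal) channel."""
    spec.validate()
    rec = gen_background(spec)
    samples = rec.samples.copy()
    rng = np.random.default_rng(spec.seed + 10_000)
    events = []
    for sz in spec.seizures:
        i0 = int(round(sz.onset_s * spec.fs))
        for c in range(rec.n_channels):
            w = _seizure_waveform(rng, spec.fs, sz)
            samples[c, i0:i0 + len(w)] += w * UV
        events.append(Event(sz.onset_s, sz.onset_s + sz.duration_s, "seizure"))
    blink = _blink_train(np.random.default_rng(spec.seed + 20_000), spec)
    samples[0] += blink * UV
    return rec.copy_with(samples=samples, events=EventList(events))


def gen_seizure_dataset(spec: SynthSpec, n_records: int) -> list[Recording]:
    """Sequence of records sharing one spec; per-record seeds are derived
    as ``seed + index`` so records are independent but reproducible.
    Seizure onsets/durations in ``spec.seizures`` apply to every record
    unless ``spec`` is replaced per record by the caller."""
    from dataclasses import replace

    out = []
    for k in range(n_records):
        out.append(gen_seizure_record(replace(spec, seed=spec.seed + k)))
    return out


def default_seizure_dataset(seed: int = 0, n_records: int = 10,
                            record_s: float = 3600.0, fs: float = 128.0
                            ) -> list[Recording]:
    """The package's reference synthetic seizure corpus: ``n_records``
    one-hour, two-bipolar-channel records with 12 seizures in total
    (records 0 and 9 carry two, the rest one each), 60 s ictal events of
    4 Hz discharges at 100 µV over a 20 µV 1/f background."""
    from dataclasses import replace

    per_record = [2] + [1] * (n_records - 2) + [2] if n_records >= 2 else [12]
    rng = np.random.default_rng(seed + 500_000)
    # event geometry scales down with short records (desk-scale corpora)
    dur = min(60.0, record_s / 6.0)
    margin = min(120.0, record_s / 10.0)
    sep = min(300.0, record_s / 2.5)
    records = []
    for k in range(n_records):
        n_sz = per_record[k] if k < len(per_record) else 1
        # onsets with >= sep separation, events inside [margin, end-margin]
        hi = record_s - margin - dur - sep * (n_sz - 1)
        if hi <= margin:
            raise ValueError(
                f"record of {record_s:g} s too short for {n_sz} seizures"
            )
        onsets = np.sort(rng.uniform(margin, hi, size=n_sz))
        onsets = onsets + sep * np.arange(n_sz)
        szs = tuple(SeizureSpec(float(o), dur, 4.0, 100.0) for o in onsets)
        spec = SynthSpec(fs=fs, duration_s=record_s, seizures=szs,
                         background_rms_uv=20.0, blink_rate_per_min=0.5,
                         blink_uv=120.0, noise_rms_uv=1.0, seed=seed + k)
        records.append(gen_seizure_record(spec))
    return records


def gen_dual_device(rec: Recording, fs2: float, jitter_s: float = 0.0,
                    gain2: float = 1.0, noise2_uv: float = 0.0,
                    seed: int = 0) -> Recording:
    """Second-device view of the same physiology: band-limited resampling
    to ``fs2``, a constant timing offset, a gain mismatch, and additive
    sensor noise."""
    if fs2 <= 0:
        raise ValueError(f"fs2 must be positive, got {fs2}")
    if (fs2 == rec.fs and jitter_s == 0.0 and gain2 == 1.0
            and noise2_uv == 0.0):
        return rec.copy_with(samples=rec.samples.copy())
    from fractions import Fraction

    frac = Fraction(fs2 / rec.fs).limit_denominator(1000)
    x = signal.resample_poly(rec.samples, frac.numerator, frac.denominator,
                             axis=1)
    if jitter_s:
        shift = int(round(jitter_s * fs2))
        x = np.roll(x, shift, axis=1)
    x = x * gain2
    if noise2_uv:
        rng = np.random.default_rng(seed)
        x = x + rng.standard_normal(x.shape) * noise2_uv * UV
    return Recording(x, fs2, list(rec.channel_labels), montage=rec.montage,
                     start_time=rec.start_time, events=rec.events)


def gen_noise_floor(spec: SynthSpec,
                    acq: AcquisitionSpec | None = None) -> Recording:
    """Shorted-input bench stream: zero-mean Gaussian noise at the
    configured RMS, quantized at the front end's input-referred code width.

    Warns when fewer than 10,000 samples are produced — the guideline
    sample count for a stable noise estimate."""
    spec.validate()
    acq = acq or AcquisitionSpec()
    n = _n_samples(spec)
    if n < 10_000:
        warnings.warn(
            f"{n} samples generated; noise estimates are recommended on "
            ">= 10,000 consecutive samples"
        )
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal((len(spec.channel_labels), n)) * spec.noise_rms_uv * UV
    x = _quantize(x, acq.resolution)
    return Recording(x, spec.fs, list(spec.channel_labels))


def gen_common_mode_stream(fs: float, duration_s: float, test_freq: float,
                           residual_uv_peak: float, noise_rms_uv: float = 0.05,
                           seed: int = 0) -> Recording:
    """Bench stream for rejection-ratio tests: the residual of an injected
    common-mode sinusoid as seen at the amplifier input (already
    input-referred), plus a white noise floor."""
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    x = residual_uv_peak * np.sin(2 * np.pi * test_freq * t)
    x = x + rng.standard_normal(n) * noise_rms_uv
    return Recording(x[None, :] * UV, fs, ["CM"])
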