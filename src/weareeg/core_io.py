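"""Recordings, event annotations, and readers/writers for EDF, CSV and
plain-text seizure summaries.

Conventions used throughout the package:

* time is in seconds, 0-based from record start, intervals half-open
  ``[onset, offset)``;
* amplitudes are stored in **volts** internally (microvolts appear only at
  presentation time);
* channel labels follow the 10-20 system, upper-cased except the trailing
  lower-case hemisphere letter convention is ignored: ``F7``, ``T7``,
  bipolar derivations are written without separator (``F7T7``).
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class UnsupportedLayoutError(ValueError):
    """A file is well-formed but uses a layout this package does not handle."""


# ---------------------------------------------------------------------------
# Events


@dataclass(frozen=True)
class Event:
    onset_s: float
    offset_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"event onset ({self.onset_s}) must precede offset ({self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "Event") -> bool:
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s


class EventList:
    """Sorted list of labelled ``[onset, offset)`` intervals.

    Overlapping (or touching) events sharing a label are merged on
    construction, so an EventList is always a set of disjoint intervals
    per label.
    """

    def __init__(self, events: Iterable[Event] = ()):
        self.events: list[Event] = _merge_events(events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventList) and self.events == other.events

    def __repr__(self) -> str:
        return f"EventList({self.events!r})"

    def with_label(self, label: str) -> "EventList":
        return EventList(e for e in self.events if e.label == label)

    def shifted(self, dt_s: float) -> "EventList":
        return EventList(
            Event(e.onset_s + dt_s, e.offset_s + dt_s, e.label) for e in self.events
        )


def _merge_events(events: Iterable[Event]) -> list[Event]:
    by_label: dict[str, list[Event]] = {}
    for e in events:
        by_label.setdefault(e.label, []).append(e)
    merged: list[Event] = []
    for label, evs in by_label.items():
        evs.sort(key=lambda e: e.onset_s)
        cur = evs[0]
        for e in evs[1:]:
            if e.onset_s <= cur.offset_s:  # overlap or touch -> merge
                cur = Event(cur.onset_s, max(cur.offset_s, e.offset_s), label)
            else:
                merged.append(cur)
                cur = e
        merged.append(cur)
    merged.sort(key=lambda e: (e.onset_s, e.offset_s, e.label))
    return merged


# ---------------------------------------------------------------------------
# Recording


def normalize_label(raw: str) -> str:
    """Normalize a channel label to canonical 10-20 form.

    ``"f7-t7"`` and ``"F7-T7"`` both map to the bipolar name ``F7T7``;
    referential labels keep their plain name (``"Fp1 "`` -> ``FP1``).
    """
    s = raw.strip().upper().replace(" ", "")
    if "-" in s:
        a, _, b = s.partition("-")
        return a + b
    return s


def _is_bipolar_label(raw: str) -> bool:
    return "-" in raw.strip()


@dataclass
class Recording:
    """Uniformly sampled multichannel recording with annotations.

    ``samples`` has shape (n_channels, n_samples) in volts.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    montage: str = "referential"  # "referential" | "bipolar"
    start_time: float = 0.0
    events: EventList = field(default_factory=EventList)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.montage not in ("referential", "bipolar"):
            raise ValueError(f"unknown montage kind {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        label = normalize_label(label)
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present; have {self.channel_labels}"
            ) from None
        return self.samples[idx]

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


def to_bipolar(rec: Recording, pairs: Sequence[tuple[str, str]]) -> Recording:
    """Re-reference a referential recording to bipolar derivations.

    Each output channel is ``anode - cathode`` sample-wise, which cancels
    the shared reference potential.
    """
    if rec.montage != "referential":
        raise ValueError("to_bipolar expects a referential-montage recording")
    out = np.empty((len(pairs), rec.n_samples))
    labels = []
    for i, (anode, cathode) in enumerate(pairs):
        out[i] = rec.channel(anode) - rec.channel(cathode)
        labels.append(normalize_label(anode) + normalize_label(cathode))
    return Recording(
        out, rec.fs, labels, montage="bipolar",
        start_time=rec.start_time, events=rec.events,
    )


# ---------------------------------------------------------------------------
# EDF (16-bit, plain EDF; annotations travel in separate summary files)

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_edf(path: str | Path, rec: Recording, physical_dim: str = "uV") -> None:
    """Write a Recording as plain 16-bit EDF.

    One data record per second; the signal is truncated to a whole number
    of seconds (with a warning) because EDF stores a fixed sample count per
    record. Amplitudes are scaled to microvolts on disk (``physical_dim``).
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise UnsupportedLayoutError(
            f"EDF writer requires an integer sampling rate, got {fs}"
        )
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        warnings.warn(
            f"truncating {rec.n_samples - n_rec * spr} trailing samples "
            "to fill whole 1-s EDF records"
        )
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data_uv = rec.samples[:, : n_rec * spr] * 1e6

    # per-channel physical scaling
    phys_min = np.floor(data_uv.min(axis=1))
    phys_max = np.ceil(data_uv.max(axis=1))
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    def pad(text: str, n: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > n:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(n)

    hdr = io.BytesIO()
    hdr.write(pad("0", 8))                       # version
    hdr.write(pad("X X X X", 80))                # patient id (anonymous)
    hdr.write(pad("Startdate X X X X", 80))      # recording id
    hdr.write(pad("01.01.00", 8))                # start date
    hdr.write(pad("00.00.00", 8))                # start time
    hdr.write(pad(str(256 * (nch + 1)), 8))      # header bytes
    hdr.write(pad("", 44))                       # reserved
    hdr.write(pad(str(n_rec), 8))                # number of data records
    hdr.write(pad("1", 8))                       # record duration (s)
    hdr.write(pad(str(nch), 4))                  # number of signals

    def disk_label(lbl: str) -> str:
        # restore the conventional "-" separator for bipolar derivations
        if rec.montage == "bipolar" and len(lbl) >= 4:
            return f"{lbl[:len(lbl)//2]}-{lbl[len(lbl)//2:]}"
        return lbl

    for lbl in rec.channel_labels:
        hdr.write(pad(disk_label(lbl), 16))
    for _ in range(nch):
        hdr.write(pad("AgAgCl electrode", 80))   # transducer
    for _ in range(nch):
        hdr.write(pad(physical_dim, 8))
    for i in range(nch):
        hdr.write(pad(_fmt_float(phys_min[i]), 8))
    for i in range(nch):
        hdr.write(pad(_fmt_float(phys_max[i]), 8))
    for _ in range(nch):
        hdr.write(pad(str(_EDF_DIG_MIN), 8))
    for _ in range(nch):
        hdr.write(pad(str(_EDF_DIG_MAX), 8))
    for _ in range(nch):
        hdr.write(pad("", 80))                   # prefiltering
    for _ in range(nch):
        hdr.write(pad(str(spr), 8))              # samples per record
    for _ in range(nch):
        hdr.write(pad("", 32))                   # reserved

    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (data_uv - phys_min[:, None]) * gain[:, None] + _EDF_DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr.getvalue())
        # records are channel-blocked: ch0[spr], ch1[spr], ... per record
        blocked = digital.reshape(nch, n_rec, spr).transpose(1, 0, 2)
        f.write(blocked.tobytes())


def _fmt_float(x: float) -> str:
    s = f"{x:.8g}"
    if len(s) > 8:
        s = f"{x:.2e}"
    return s[:8]


def read_edf(path: str | Path) -> Recording:
    """Read a plain EDF file into a Recording (amplitudes in volts).

    Labels are normalized (``"F7-T7"`` -> ``F7T7``); the montage is flagged
    bipolar when every label carries a ``-`` separator. All channels must
    share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size < 256:
        raise FormatError(f"{path}: file too short to hold an EDF header")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad headers
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    sf = raw.info["sfreq"]
    raw_labels = list(raw.ch_names)
    bipolar = all(_is_bipolar_label(l) for l in raw_labels) and raw_labels
    labels = [normalize_label(l) for l in raw_labels]
    return Recording(
        raw.get_data(), float(sf), labels,
        montage="bipolar" if bipolar else "referential",
    )


# ---------------------------------------------------------------------------
# Annotation summaries (CHB-MIT plain-text dialect)


def write_annotation_summary(
    path: str | Path, events: EventList, file_name: str = ""
) -> None:
    seiz = [e for e in events if e.label == "seizure"]
    lines = []
    if file_name:
        lines.append(f"File Name: {file_name}")
    lines.append(f"Number of Seizures in File: {len(seiz)}")
    for i, e in enumerate(seiz, start=1):
        lines.append(f"Seizure {i} Start Time: {_fmt_seconds(e.onset_s)} seconds")
        lines.append(f"Seizure {i} End Time: {_fmt_seconds(e.offset_s)} seconds")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_seconds(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def read_annotation_summary(path: str | Path) -> EventList:
    """Parse a plain-text seizure summary into an EventList.

    Accepts the CHB-MIT dialect: ``Seizure [N ]Start Time: X seconds`` /
    ``Seizure [N ]End Time: Y seconds`` pairs, offsets relative to record
    start. Overlapping intervals merge (EventList semantics).
    """
    starts: list[tuple[int, float]] = []
    ends: list[tuple[int, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        low = line.lower()
        if "seizure" not in low or "time:" not in low:
            continue
        try:
            value = float(low.split("time:")[1].replace("seconds", "").strip())
        except ValueError:
            raise FormatError(f"{path}:{lineno}: unreadable time in {line!r}")
        if "start time" in low:
            starts.append((lineno, value))
        elif "end time" in low:
            ends.append((lineno, value))
    if len(starts) != len(ends):
        raise FormatError(
            f"{path}: {len(starts)} seizure starts but {len(ends)} ends"
        )
    events = []
    for (sline, s), (eline, e) in zip(starts, ends):
        if e <= s:
            raise FormatError(
                f"{path}:{eline}: seizure end {e} not after start {s}"
            )
        events.append(Event(s, e, "seizure"))
    return EventList(events)


# ---------------------------------------------------------------------------
# CSV (header row = labels, first column = time in seconds)


def write_csv(path: str | Path, rec: Recording) -> None:
    t = np.arange(rec.n_samples) / rec.fs + rec.start_time
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_s", *rec.channel_labels])
        for i in range(rec.n_samples):
            w.writerow([f"{t[i]:.9g}", *(f"{v:.9g}" for v in rec.samples[:, i])])


def read_csv(path: str | Path) -> Recording:
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus >=1 channel")
    if df.shape[0] < 2:
        raise FormatError(f"{path}: need >=2 samples to infer the rate")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise UnsupportedLayoutError(f"{path}: time column is not uniform")
    labels = [normalize_label(c) for c in df.columns[1:]]
    bipolar = all(_is_bipolar_label(c) for c in df.columns[1:])
    return Recording(
        df.iloc[:, 1:].to_numpy(dtype=float).T,
        1.0 / dt[0],
        labels,
        montage="bipolar" if bipolar else "referential",
        start_time=float(t[0]),
    )


# ---------------------------------------------------------------------------
# Acquisition front-end description


@dataclass(frozen=True)
class AcquisitionSpec:
    """Static description of one ADC front-end configuration.

    resolution is derived as ``2*vref / (pga_gain * 2**bits)`` (volts per
    code at the amplifier input) unless given explicitly.
    """

    fs: float = 250.0
    pga_gain: float = 24.0
    vref: float = 4.5
    bits: int = 24
    resolution: float | None = None

    def __post_init__(self) -> None:
        derived = 2 * self.vref / (self.pga_gain * 2**self.bits)
        if self.resolution is None:
            object.__setattr__(self, "resolution", derived)
        elif not math.isclose(self.resolution, derived, rel_tol=0.05):
            raise ValueError(
                f"stated resolution {self.resolution:g} V/bit inconsistent with "
                f"2*vref/(gain*2^bits) = {derived:g} V/bit"
            )
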