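"""Interictal segment selection and extraction.

Given an annotated exam timeline (consciousness-state intervals, seizure
events, sampling-rate intervals), this module locates periods that satisfy
a :class:`SelectionPolicy`, places fixed-length segments inside them under
a minimum-separation constraint, extracts the segments from recordings,
and flags unsuitable channels using simple spectral rules.

All times are seconds from the start of the exam; intervals are half-open
``[start, end)``.  Clock-of-day constraints are resolved against the exam
start datetime (timezone-naive).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

from normkit.io import Recording, read_container, write_container

#: Accepted consciousness states (standard sleep stages + wake + unknown).
STATES = ("W", "N1", "N2", "N3", "R", "NA")

#: Accepted seizure types.
SEIZURE_TYPES = ("focal", "subclin", "sg")

Interval = tuple[float, float]


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def normalize_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort, drop empties and merge overlapping/adjacent intervals."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    merged: list[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    a, b = normalize_intervals(a), normalize_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Set difference a \\ b over half-open intervals."""
    a = normalize_intervals(a)
    b = normalize_intervals(b)
    out: list[Interval] = []
    for lo, hi in a:
        cur = lo
        for blo, bhi in b:
            if bhi <= cur or blo >= hi:
                continue
            if blo > cur:
                out.append((cur, blo))
            cur = max(cur, bhi)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
    return out


def total_duration(intervals: Iterable[Interval]) -> float:
    return sum(b - a for a, b in intervals)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeizureEvent:
    onset: float
    duration: float = 0.0
    type: str = "focal"
    onset_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("seizure duration must be >= 0")


@dataclass
class ExamTimeline:
    """Annotations of one icEEG exam.

    ``state_intervals`` and ``fs_intervals`` are half-open, sorted and
    non-overlapping; seizures lie within the exam span.
    """

    state_intervals: list[tuple[float, float, str]]
    seizures: list[SeizureEvent] = field(default_factory=list)
    implant_time: float = 0.0
    fs_intervals: list[tuple[float, float, float]] = field(default_factory=list)
    exam_start: str = "1970-01-01T00:00:00"

    def __post_init__(self) -> None:
        self.state_intervals = sorted(self.state_intervals)
        prev_end = -math.inf
        for a, b, s in self.state_intervals:
            if b <= a:
                raise ValueError("state intervals must be non-empty half-open")
            if a < prev_end:
                raise ValueError("state intervals must not overlap")
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")
            prev_end = b
        span = self.span
        for sz in self.seizures:
            if not (span[0] <= sz.onset <= span[1]):
                raise ValueError("seizure onset outside exam span")

    @property
    def span(self) -> Interval:
        if not self.state_intervals:
            return (0.0, 0.0)
        return self.state_intervals[0][0], self.state_intervals[-1][1]

    @property
    def exam_start_datetime(self) -> _dt.datetime:
        return _dt.datetime.fromisoformat(self.exam_start)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "exam_start": self.exam_start,
            "implant_time": self.implant_time,
            "state_intervals": [[a, b, s] for a, b, s in self.state_intervals],
            "fs_intervals": [[a, b, fs] for a, b, fs in self.fs_intervals],
            "seizures": [
                {
                    "onset": sz.onset,
                    "duration": sz.duration,
                    "type": sz.type,
                    "onset_channels": list(sz.onset_channels),
                }
                for sz in self.seizures
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExamTimeline":
        return cls(
            state_intervals=[(float(a), float(b), s) for a, b, s in d["state_intervals"]],
            seizures=[
                SeizureEvent(
                    onset=float(sz["onset"]),
                    duration=float(sz.get("duration", 0.0)),
                    type=sz.get("type", "focal"),
                    onset_channels=tuple(sz.get("onset_channels", ())),
                )
                for sz in d.get("seizures", [])
            ],
            implant_time=float(d.get("implant_time", 0.0)),
            fs_intervals=[(float(a), float(b), float(fs)) for a, b, fs in d.get("fs_intervals", [])],
            exam_start=d.get("exam_start", "1970-01-01T00:00:00"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExamTimeline":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SelectionPolicy:
    """Segment-selection constraints.

    Durations: ``seizure_buffer``, ``min_separation`` and
    ``post_implant_skip`` are in hours; ``segment_length`` is in seconds.
    ``seizure_buffer`` may be a single number applied to every seizure type
    or a per-type mapping.  ``separation_mode`` controls whether the
    minimum separation is measured start-to-start (default) or end-to-start
    ("gap").
    """

    state: str = "W"
    seizure_buffer: float | Mapping[str, float] = 2.0
    min_fs: float = 200.0
    segment_length: float = 70.0
    n_segments: int = 3
    min_separation: float = 4.0
    post_implant_skip: float = 24.0
    time_of_day_window: tuple[str, str] | None = None
    separation_mode: str = "start"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.segment_length <= 0 or self.min_separation <= 0:
            raise ValueError("durations must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.separation_mode not in ("start", "gap"):
            raise ValueError("separation_mode must be 'start' or 'gap'")

    def buffer_seconds(self, seizure_type: str) -> float:
        if isinstance(self.seizure_buffer, Mapping):
            if seizure_type not in self.seizure_buffer:
                raise KeyError(f"no buffer configured for seizure type {seizure_type!r}")
            return float(self.seizure_buffer[seizure_type]) * 3600.0
        return float(self.seizure_buffer) * 3600.0

    def to_dict(self) -> dict:
        d = {
            "state": self.state,
            "seizure_buffer": dict(self.seizure_buffer)
            if isinstance(self.seizure_buffer, Mapping)
            else self.seizure_buffer,
            "min_fs": self.min_fs,
            "segment_length": self.segment_length,
            "n_segments": self.n_segments,
            "min_separation": self.min_separation,
            "post_implant_skip": self.post_implant_skip,
            "time_of_day_window": list(self.time_of_day_window)
            if self.time_of_day_window
            else None,
            "separation_mode": self.separation_mode,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionPolicy":
        d = dict(d)
        if d.get("time_of_day_window"):
            d["time_of_day_window"] = tuple(d["time_of_day_window"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown policy keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SegmentRecord:
    """One extracted fixed-length interictal segment plus its metadata."""

    channel_names: list[str]
    data: np.ndarray
    fs: float
    start_datetime: str
    duration: float
    wake_status: str
    subject_id: str
    hospital: str
    segment_number: int
    unsuitable_channel_names: list[str] = field(default_factory=list)
    spiking_channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("data row count must equal |channel_names|")
        names = set(self.channel_names)
        if not set(self.unsuitable_channel_names) <= names:
            raise ValueError("unsuitable_channel_names must be a subset of channel_names")
        if not set(self.spiking_channel_names) <= names:
            raise ValueError("spiking_channel_names must be a subset of channel_names")
        if abs(self.duration * self.fs - self.data.shape[1]) > 1:
            raise ValueError("duration * fs must match sample count (within 1 sample)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def subset(self, names: Sequence[str]) -> "SegmentRecord":
        """A copy restricted to ``names`` (order preserved as given)."""
        idx = [self.channel_names.index(n) for n in names]
        keep = set(names)
        return replace(
            self,
            channel_names=list(names),
            data=self.data[idx].copy(),
            unsuitable_channel_names=[n for n in self.unsuitable_channel_names if n in keep],
            spiking_channel_names=[n for n in self.spiking_channel_names if n in keep],
        )

    def metadata(self) -> dict:
        return {
            "channel_names": self.channel_names,
            "unsuitable_channel_names": self.unsuitable_channel_names,
            "spiking_channel_names": self.spiking_channel_names,
            "start_datetime": self.start_datetime,
            "duration": self.duration,
            "fs": self.fs,
            "wake_status": self.wake_status,
            "subject_id": self.subject_id,
            "hospital": self.hospital,
            "segment_number": self.segment_number,
        }

    def save(self, path: str | Path) -> None:
        """Write the container plus a JSON metadata sidecar."""
        path = Path(path)
        rec = Recording(
            data=self.data,
            fs=self.fs,
            channel_names=self.channel_names,
            start_datetime=self.start_datetime,
        )
        write_container(path, rec)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.metadata(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentRecord":
        path = Path(path)
        rec = read_container(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            channel_names=list(meta["channel_names"]),
            data=rec.data,
            fs=float(meta["fs"]),
            start_datetime=meta["start_datetime"],
            duration=float(meta["duration"]),
            wake_status=meta["wake_status"],
            subject_id=meta["subject_id"],
            hospital=meta["hospital"],
            segment_number=int(meta["segment_number"]),
            unsuitable_channel_names=list(meta["unsuitable_channel_names"]),
            spiking_channel_names=list(meta["spiking_channel_names"]),
        )


# ---------------------------------------------------------------------------
# selection operations
# ---------------------------------------------------------------------------

def state_periods(timeline: ExamTimeline, policy: SelectionPolicy) -> list[Interval]:
    """Periods in the requested state, after the post-implantation skip and
    inside the optional clock-time window."""
    matching = [(a, b) for a, b, s in timeline.state_intervals if s == policy.state]
    skip_from = timeline.implant_time + policy.post_implant_skip * 3600.0
    out = intersect_intervals(matching, [(skip_from, math.inf)])
    if policy.time_of_day_window is not None:
        out = intersect_intervals(out, _daily_windows(timeline, policy.time_of_day_window))
    return out


def _daily_windows(timeline: ExamTimeline, window: tuple[str, str]) -> list[Interval]:
    """Expand a clock-time window into exam-second intervals across the exam."""
    start_dt = timeline.exam_start_datetime
    t0, t1 = (_dt.time.fromisoformat(t) for t in window)
    span_lo, span_hi = timeline.span
    day0 = _dt.datetime.combine(start_dt.date(), _dt.time())
    out = []
    day = -1
    while True:
        base = day0 + _dt.timedelta(days=day)
        lo = (base + _dt.timedelta(hours=t0.hour, minutes=t0.minute, seconds=t0.second) - start_dt).total_seconds()
        hi = (base + _dt.timedelta(hours=t1.hour, minutes=t1.minute, seconds=t1.second) - start_dt).total_seconds()
        if hi < lo:  # window crosses midnight
            hi += 86400.0
        if lo > span_hi:
            break
        out.append((lo, hi))
        day += 1
    return intersect_intervals(out, [(span_lo, span_hi)])


def remove_seizure_buffer(
    intervals: Iterable[Interval],
    seizures: Sequence[SeizureEvent],
    buffer: float | Mapping[str, float],
) -> list[Interval]:
    """Subtract a guard window around every seizure.

    ``buffer`` is in seconds, either one value for all seizure types or a
    per-type mapping (unknown types are rejected).  The excluded window is
    ``[onset - buffer, onset + duration + buffer)``.
    """
    forbidden = []
    for sz in seizures:
        if sz.type not in SEIZURE_TYPES:
            raise ValueError(f"unknown seizure type {sz.type!r}")
        if isinstance(buffer, Mapping):
            if sz.type not in buffer:
                raise ValueError(f"no buffer configured for seizure type {sz.type!r}")
            buf = float(buffer[sz.type])
        else:
            buf = float(buffer)
        forbidden.append((sz.onset - buf, sz.onset + sz.duration + buf))
    return subtract_intervals(intervals, forbidden)


def filter_periods(
    intervals: Iterable[Interval],
    timeline: ExamTimeline,
    policy: SelectionPolicy,
) -> list[Interval]:
    """Drop interval pieces below the sampling-rate floor or shorter than
    one segment length."""
    fs_ok = [(a, b) for a, b, fs in timeline.fs_intervals if fs >= policy.min_fs]
    if timeline.fs_intervals:
        intervals = intersect_intervals(intervals, fs_ok)
    else:
        intervals = normalize_intervals(intervals)
    return [(a, b) for a, b in intervals if b - a >= policy.segment_length]


def suitable_periods(timeline: ExamTimeline, policy: SelectionPolicy) -> list[Interval]:
    """Compose the full period pipeline: state -> seizure buffers -> fs and
    length filters."""
    buf: float | dict[str, float]
    if isinstance(policy.seizure_buffer, Mapping):
        buf = {t: policy.buffer_seconds(t) for t in policy.seizure_buffer}
    else:
        buf = float(policy.seizure_buffer) * 3600.0
    periods = state_periods(timeline, policy)
    periods = remove_seizure_buffer(periods, timeline.seizures, buf)
    return filter_periods(periods, timeline, policy)


def select_segments(
    intervals: Iterable[Interval], policy: SelectionPolicy
) -> list[float]:
    """Greedy earliest-first placement of fixed-length segments.

    Returns up to ``n_segments`` start times; each placement lies fully
    inside one interval and consecutive placements respect the minimum
    separation.  Returns fewer placements when the constraint set is
    infeasible; never raises for a shortfall.
    """
    sep = policy.min_separation * 3600.0
    length = policy.segment_length
    placements: list[float] = []
    for a, b in normalize_intervals(intervals):
        while len(placements) < policy.n_segments:
            if placements:
                anchor = placements[-1] + sep
                if policy.separation_mode == "gap":
                    anchor += length
            else:
                anchor = -math.inf
            start = max(a, anchor)
            if start + length > b:
                break
            placements.append(start)
            a = start  # next candidate constrained by separation from here
        if len(placements) >= policy.n_segments:
            break
    return placements


def extract_segment(
    recording: Recording,
    placement: float,
    policy: SelectionPolicy,
    *,
    subject_id: str,
    hospital: str,
    segment_number: int,
    exam_start: str = "1970-01-01T00:00:00",
    spiking_channel_names: Sequence[str] = (),
    unsuitable_channel_names: Sequence[str] = (),
) -> SegmentRecord:
    """Slice one fixed-length segment out of a recording excerpt.

    ``placement`` is in exam seconds; the recording's ``exam_offset`` maps
    it to a local sample index.
    """
    length = policy.segment_length
    lo, hi = recording.span
    if placement < lo - 0.5 / recording.fs or placement + length > hi + 0.5 / recording.fs:
        raise IndexError(
            f"placement [{placement}, {placement + length}) outside recording span [{lo}, {hi})"
        )
    i0 = int(round((placement - recording.exam_offset) * recording.fs))
    n = int(round(length * recording.fs))
    i0 = max(i0, 0)
    if i0 + n > recording.n_samples:
        raise IndexError("placement extends past end of recording")
    start_dt = _dt.datetime.fromisoformat(exam_start) + _dt.timedelta(seconds=placement)
    return SegmentRecord(
        channel_names=list(recording.channel_names),
        data=recording.data[:, i0 : i0 + n].copy(),
        fs=recording.fs,
        start_datetime=start_dt.isoformat(),
        duration=length,
        wake_status=policy.state,
        subject_id=subject_id,
        hospital=hospital,
        segment_number=segment_number,
        spiking_channel_names=list(spiking_channel_names),
        unsuitable_channel_names=list(unsuitable_channel_names),
    )


# ---------------------------------------------------------------------------
# channel quality flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlagRules:
    """Rules for automatic unsuitable-channel flagging.

    A channel is flagged when it is flat (zero variance), when the robust
    z-score of its log total power across channels exceeds ``power_z_max``,
    or when its log-PSD/log-frequency slope is >= ``slope_max`` (clean
    channels follow a decaying 1/f-like spectrum).
    """

    power_z_max: float = 3.0
    #: a power outlier must also differ from the median total power by
    #: this factor (guards near-homogeneous montages with tiny MAD)
    power_min_ratio: float = 3.0
    #: clean channels show steeply decaying (1/f-like) spectra; a log-log
    #: slope shallower than this marks a non-physiological channel
    slope_max: float = -0.5
    slope_fit_range: tuple[float, float] = (2.0, 45.0)
    welch_window_s: float = 2.0


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        out = np.zeros_like(values, dtype=float)
        off = values != med
        out[off] = np.sign(values[off] - med) * np.inf
        return out
    return (values - med) / scale


def flag_unsuitable_channels(
    segment: SegmentRecord, rules: FlagRules = FlagRules()
) -> list[str]:
    """Flag flatlined, outlier-power and non-1/f channels.

    The returned names are also recorded in
    ``segment.unsuitable_channel_names`` (union with any existing flags).
    """
    if len(segment.channel_names) < 2:
        raise ValueError("need at least 2 channels for cross-channel reference")
    nperseg = min(int(rules.welch_window_s * segment.fs), segment.n_samples)
    if segment.n_samples < 2 * nperseg:
        raise ValueError("segment too short for two Welch windows")
    freqs, psd = _sig.welch(
        segment.data, fs=segment.fs, window="hamming", nperseg=nperseg
    )
    flagged: set[str] = set()
    variances = segment.data.var(axis=1)
    for name, var in zip(segment.channel_names, variances):
        if var == 0:
            flagged.add(name)

    live = [i for i, v in enumerate(variances) if v > 0]
    if live:
        log_total = np.log10(psd[live].sum(axis=1))
        z = np.abs(_robust_z(log_total))
        big = np.abs(log_total - np.median(log_total)) > np.log10(rules.power_min_ratio)
        for idx, zi, bi in zip(live, z, big):
            if zi > rules.power_z_max and bi:
                flagged.add(segment.channel_names[idx])
        lo, hi = rules.slope_fit_range
        fit = (freqs >= lo) & (freqs <= min(hi, 0.95 * segment.fs / 2)) & (freqs > 0)
        logf = np.log10(freqs[fit])
        for idx in live:
            p = psd[idx, fit]
            if np.any(p <= 0):
                continue
            slope = _stats.linregress(logf, np.log10(p)).slope
            if slope >= rules.slope_max:
                flagged.add(segment.channel_names[idx])

    out = sorted(flagged)
    segment.unsuitable_channel_names = sorted(
        set(segment.unsuitable_channel_names) | flagged
    )
    return out
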