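"""Recording containers.

Recordings and extracted segments are stored in an HDF5 container with a
single ``data`` dataset (channels x samples) and scalar/string attributes
for sampling rate, start datetime, channel names and the offset of the
recording from the start of the exam.  HDF5 timestamp tracking is disabled
so containers are byte-reproducible.

EDF import is available when ``pyedflib`` is installed (optional extra).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np


@dataclass
class Recording:
    """A multichannel recording excerpt.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling frequency in Hz.
    channel_names
        One name per data row.
    start_datetime
        ISO-8601 datetime of the first sample.
    exam_offset
        Seconds between the start of the exam and the first sample of this
        excerpt.  Placements produced by segment selection are expressed in
        exam time, so extraction subtracts this offset.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    start_datetime: str = "1970-01-01T00:00:00"
    exam_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count must equal number of channel names")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the excerpt in exam seconds, half-open."""
        return self.exam_offset, self.exam_offset + self.duration


def write_container(path: str | Path, rec: Recording) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        dset = f.create_dataset("data", data=rec.data, track_times=False)
        dset.attrs["fs"] = float(rec.fs)
        dset.attrs["start_datetime"] = rec.start_datetime
        dset.attrs["exam_offset"] = float(rec.exam_offset)
        dset.attrs["channel_names"] = json.dumps(rec.channel_names)


def read_container(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        dset = f["data"]
        return Recording(
            data=dset[()],
            fs=float(dset.attrs["fs"]),
            channel_names=list(json.loads(dset.attrs["channel_names"])),
            start_datetime=str(dset.attrs["start_datetime"]),
            exam_offset=float(dset.attrs["exam_offset"]),
        )


def read_edf(path: str | Path, channels: Sequence[str] | None = None) -> Recording:
    """Load an EDF recording (requires the ``pyedflib`` optional extra)."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF import requires pyedflib; install normkit[edf]"
        ) from exc
    with pyedflib.EdfReader(str(path)) as r:  # pragma: no cover
        labels = r.getSignalLabels()
        idx = range(len(labels)) if channels is None else [
            labels.index(c) for c in channels
        ]
        data = np.vstack([r.readSignal(i) for i in idx])
        fs = float(r.getSampleFrequency(next(iter(idx))))
        start = r.getStartdatetime().isoformat()
        names = [labels[i] for i in idx]
    return Recording(data=data, fs=fs, channel_names=names, start_datetime=start)
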