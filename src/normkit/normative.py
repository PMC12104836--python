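"""Regional normative mapping of log relative band power.

The normative pipeline, per subject and segment: drop channels marked
pathological (resected / spiking / structurally abnormal / within the
seizure-onset zone) or unlocalised; drop algorithmically noisy channels;
re-reference to the common average of the retained channels; band-pass and
notch filter; resample to a common rate; compute relative band power (RBP)
per channel via Welch's method; average RBP across a region's channels and
take log10; remove regional leave-one-out outliers across the cohort; and
summarise each (region, band) cell as mean/SD/n of log10(RBP) over
subjects.

Several constants here (noisy-channel rule, filter settings, log base,
leave-one-out threshold) are documented stand-ins: the upstream protocol
names these decision points without printing exact values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from normkit.bands import BandScheme, DEFAULT_BANDS
from normkit.spatial import FLAG_COLUMNS
from normkit.temporal import SegmentRecord, _robust_z

logger = logging.getLogger(__name__)

REFERENCES = ("common_average", "bipolar", "none")


@dataclass(frozen=True)
class PreprocessParams:
    """Signal conditioning applied before the band-power metric."""

    reference: str = "common_average"
    bandpass: tuple[float, float] = (0.5, 47.5)
    bandpass_order: int = 4
    notch_base: float = 50.0
    notch_harmonics: bool = True
    notch_q: float = 30.0
    target_fs: float = 200.0

    def __post_init__(self) -> None:
        if self.reference not in REFERENCES:
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.notch_base not in (50.0, 60.0):
            raise ValueError("notch base must be 50 or 60 Hz")
        low, high = self.bandpass
        if not (0 < low < high):
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if high >= self.target_fs / 2:
            raise ValueError("bandpass high edge must be below target Nyquist")

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "bandpass": list(self.bandpass),
            "bandpass_order": self.bandpass_order,
            "notch_base": self.notch_base,
            "notch_harmonics": self.notch_harmonics,
            "notch_q": self.notch_q,
            "target_fs": self.target_fs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PreprocessParams":
        d = dict(d)
        if "bandpass" in d:
            d["bandpass"] = tuple(d["bandpass"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown preprocess keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class WelchParams:
    window_s: float = 2.0
    overlap: float = 0.5
    window: str = "hamming"

    def nperseg(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def to_dict(self) -> dict:
        return {"window_s": self.window_s, "overlap": self.overlap, "window": self.window}

    @classmethod
    def from_dict(cls, d: Mapping) -> "WelchParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown welch keys: {sorted(unknown)}")
        return cls(**d)


def metric_config_hash(
    preproc: PreprocessParams,
    bands: BandScheme = DEFAULT_BANDS,
    welch: WelchParams = WelchParams(),
) -> str:
    """Hash of every parameter that shapes the metric; abnormality scoring
    must use the identical hash as the map it scores against."""
    blob = json.dumps(
        {"preprocess": preproc.to_dict(), "bands": bands.to_dict(), "welch": welch.to_dict()},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# channel exclusion
# ---------------------------------------------------------------------------

def exclude_pathological(channel_table: pd.DataFrame) -> list[str]:
    """Channels retained for normative use.

    Drops channels with any pathology flag true (resected, spiking,
    structurally abnormal, within the SOZ) and channels without an ROI
    assignment.  Missing flag columns are treated as all-false (logged).
    """
    table = channel_table
    keep = pd.Series(True, index=table.index)
    for col in FLAG_COLUMNS:
        if col not in table.columns:
            logger.info("flag column %s absent; treating as all-false", col)
            continue
        keep &= ~table[col].fillna(False).astype(bool)
    if "roi_id" in table.columns:
        keep &= table["roi_id"].notna()
    return table.loc[keep, "name"].tolist()


def detect_noisy_channels(
    data: np.ndarray | SegmentRecord,
    channel_names: Sequence[str] | None = None,
    z_max: float = 3.0,
    min_ratio: float = 3.0,
) -> list[str]:
    """Channels whose log range or log variance is a robust outlier.

    Robust z uses the median and MAD across channels.  A channel is
    flagged when either statistic exceeds ``z_max`` in absolute value AND
    the raw statistic differs from the cross-channel median by more than a
    factor of ``min_ratio`` -- the ratio guard stops near-homogeneous
    montages (tiny MAD) from losing channels to trivial fluctuations.
    """
    if isinstance(data, SegmentRecord):
        channel_names = data.channel_names
        data = data.data
    data = np.asarray(data, dtype=float)
    if channel_names is None:
        channel_names = [str(i) for i in range(data.shape[0])]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 channels for cross-channel statistics")
    rng = np.ptp(data, axis=1)
    var = data.var(axis=1)
    flagged = np.zeros(data.shape[0], dtype=bool)
    for stat in (rng, var):
        log_stat = np.log(np.maximum(stat, 1e-300))
        z = _robust_z(log_stat)
        big = np.abs(log_stat - np.median(log_stat)) > np.log(min_ratio)
        flagged |= (np.abs(z) > z_max) & big
    return [n for n, f in zip(channel_names, flagged) if f]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def apply_reference(data: np.ndarray, reference: str = "common_average") -> np.ndarray:
    """Re-reference a channels x samples array.

    Common average subtracts the cross-channel mean at every sample, so
    the channel mean is exactly zero afterwards.
    """
    if reference == "common_average":
        return data - data.mean(axis=0, keepdims=True)
    if reference == "none":
        return data.copy()
    if reference == "bipolar":
        raise NotImplementedError("bipolar montage derivation is not implemented")
    raise ValueError(f"unknown reference {reference!r}")


def preprocess(segment: SegmentRecord, params: PreprocessParams) -> SegmentRecord:
    """Re-reference, filter and resample a segment.

    The common average is computed over the channels present in the
    segment (callers should have excluded unwanted channels first).  All
    filters are zero-phase; harmonics of the notch base are removed up to
    the analysis band edge; resampling is polyphase (anti-aliased).
    """
    fs = segment.fs
    if params.target_fs > fs:
        raise ValueError("upsampling is not supported (target_fs > native fs)")
    low, high = params.bandpass
    if high >= fs / 2:
        raise ValueError("bandpass high edge at or above native Nyquist")

    data = apply_reference(segment.data.astype(np.float64, copy=True), params.reference)

    sos = _sig.butter(params.bandpass_order, [low, high], btype="bandpass", fs=fs, output="sos")
    data = _sig.sosfiltfilt(sos, data, axis=1)

    f0 = params.notch_base
    harmonics = [f0]
    if params.notch_harmonics:
        k = 2
        while k * f0 < min(high, fs / 2):
            harmonics.append(k * f0)
            k += 1
    for f in harmonics:
        if f >= fs / 2:
            continue
        b, a = _sig.iirnotch(f, params.notch_q, fs=fs)
        data = _sig.filtfilt(b, a, data, axis=1)

    if params.target_fs != fs:
        frac = Fraction(params.target_fs / fs).limit_denominator(1000)
        data = _sig.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    new_fs = params.target_fs

    return replace(
        segment,
        data=data,
        fs=new_fs,
        duration=data.shape[1] / new_fs,
    )


# ---------------------------------------------------------------------------
# band power metric
# ---------------------------------------------------------------------------

def band_rbp(
    segment: SegmentRecord | np.ndarray,
    bands: BandScheme = DEFAULT_BANDS,
    welch: WelchParams = WelchParams(),
    fs: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative band power per channel (rows) and band (columns).

    Band power sums the Welch PSD bins whose centre frequency lies in
    ``[low, high)``; RBP divides by the total over the analysis range so
    every row sums to exactly 1.  Channels with zero total power get NaN
    rows (flagged, never +-inf downstream).
    """
    if isinstance(segment, SegmentRecord):
        data, fs, channel_names = segment.data, segment.fs, segment.channel_names
    else:
        data = np.asarray(segment, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        if channel_names is None:
            channel_names = [str(i) for i in range(data.shape[0])]
    nperseg = min(welch.nperseg(fs), data.shape[1])
    if data.shape[1] < 2 * nperseg:
        raise ValueError("segment shorter than two Welch windows")
    noverlap = int(round(nperseg * welch.overlap))
    freqs, psd = _sig.welch(data, fs=fs, window=welch.window, nperseg=nperseg, noverlap=noverlap)

    powers = np.empty((data.shape[0], len(bands.names)))
    for j, name in enumerate(bands.names):
        low, high = bands.bands[name]
        sel = (freqs >= low) & (freqs < high)
        powers[:, j] = psd[:, sel].sum(axis=1)
    total = powers.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rbp = np.where(total > 0, powers / total, np.nan)
    return pd.DataFrame(rbp, index=list(channel_names), columns=bands.names)


def band_log_rbp(
    segment: SegmentRecord | np.ndarray,
    bands: BandScheme = DEFAULT_BANDS,
    welch: WelchParams = WelchParams(),
    **kw,
) -> pd.DataFrame:
    """log10 of :func:`band_rbp` (NaN marks undefined channels)."""
    rbp = band_rbp(segment, bands, welch, **kw)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log10(rbp)


def aggregate_to_roi(
    rbp: pd.DataFrame,
    roi_of_channel: Mapping[str, int],
    reducer: Callable[[np.ndarray], float] | str = "mean",
) -> pd.DataFrame:
    """Reduce channel RBP to one log10(RBP) value per (ROI, band).

    The reducer runs in RBP space (default mean), then log10 is taken, so
    a region's value is ``log10(mean RBP of its channels)``.
    """
    unmapped = set(rbp.index) - set(roi_of_channel)
    if unmapped:
        raise ValueError(f"channels without an ROI mapping: {sorted(unmapped)}")
    groups = rbp.groupby(pd.Series(roi_of_channel).reindex(rbp.index))
    agg = groups.mean() if reducer == "mean" else groups.aggregate(reducer)
    agg.index = agg.index.astype(int)
    agg.index.name = "roi_id"
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log10(agg)


# ---------------------------------------------------------------------------
# cohort-level filtering and map construction
# ---------------------------------------------------------------------------

def loo_outlier_filter(
    rows: pd.DataFrame,
    z_max: float = 3.0,
    max_iter: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative leave-one-out outlier removal on cohort rows.

    ``rows`` is long-format with columns ``subject_id, roi_id, band,
    value``.  Per (roi, band) cell, each subject's value is z-scored
    against the leave-one-out mean/SD of the remaining subjects; a
    (subject, roi) pair with any band |z| > ``z_max`` is removed whole.
    Iterates to a fixed point (at most ``max_iter`` passes).  Cells with
    fewer than 3 subjects, or zero leave-one-out SD, produce no flags.
    Returns (retained rows, removed rows).
    """
    required = {"subject_id", "roi_id", "band", "value"}
    if not required <= set(rows.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    current = rows.copy()
    removed = []
    for _ in range(max_iter):
        to_remove: set[tuple] = set()
        for (roi, _band), grp in current.groupby(["roi_id", "band"], sort=True):
            x = grp["value"].to_numpy(dtype=float)
            n = len(x)
            if n < 3:
                continue
            for i, (subj, xi) in enumerate(zip(grp["subject_id"], x)):
                others = np.delete(x, i)
                sd = others.std(ddof=1)
                if sd == 0:
                    # zero spread: a deviating value is infinitely far out,
                    # an identical one has no finite z and is never flagged
                    if xi != others.mean():
                        to_remove.add((subj, roi))
                    continue
                if abs((xi - others.mean()) / sd) > z_max:
                    to_remove.add((subj, roi))
        if not to_remove:
            break
        mask = current.apply(
            lambda r: (r["subject_id"], r["roi_id"]) in to_remove, axis=1
        )
        removed.append(current[mask])
        current = current[~mask]
    removed_df = (
        pd.concat(removed, ignore_index=True)
        if removed
        else current.iloc[0:0].copy()
    )
    return current.reset_index(drop=True), removed_df


@dataclass
class NormativeMap:
    """Per-(ROI, band) normative distribution of log10(RBP)."""

    table: pd.DataFrame  # columns: roi_id, band, mean_log_rbp, sd_log_rbp, n
    bands: BandScheme
    provenance: dict = field(default_factory=dict)

    def cell(self, roi_id: int, band: str) -> tuple[float, float, int]:
        hit = self.table[(self.table["roi_id"] == roi_id) & (self.table["band"] == band)]
        if hit.empty:
            raise KeyError(f"({roi_id}, {band}) not in map")
        r = hit.iloc[0]
        return float(r["mean_log_rbp"]), float(r["sd_log_rbp"]), int(r["n"])

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.table["roi_id"].unique())

    @property
    def config_hash(self) -> str:
        return self.provenance.get("config_hash", "")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False, float_format="%.12g")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(
            json.dumps(
                {"bands": self.bands.to_dict(), "provenance": self.provenance},
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormativeMap":
        path = Path(path)
        table = pd.read_csv(path)
        raw = json.loads(path.with_suffix(path.suffix + ".provenance.json").read_text())
        return cls(
            table=table,
            bands=BandScheme.from_dict(raw["bands"]),
            provenance=raw["provenance"],
        )


def build_normative_map(
    rows: pd.DataFrame,
    bands: BandScheme = DEFAULT_BANDS,
    min_n: int = 30,
    config_hash: str = "",
    keep_one_segment_per_subject: bool = True,
) -> NormativeMap:
    """Summarise filtered cohort rows into the normative map.

    When segment numbers are present, only each subject's lowest surviving
    segment number contributes (backup segments are dropped).  (ROI, band)
    cells with fewer than ``min_n`` subjects are removed (logged).
    """
    rows = rows.copy()
    if keep_one_segment_per_subject and "segment_number" in rows.columns:
        first = rows.groupby("subject_id")["segment_number"].transform("min")
        rows = rows[rows["segment_number"] == first]
    grouped = rows.groupby(["roi_id", "band"], sort=True)["value"]
    table = grouped.agg(
        mean_log_rbp="mean",
        sd_log_rbp=lambda x: x.std(ddof=1),
        n="count",
    ).reset_index()
    dropped = table[table["n"] < min_n]
    if not dropped.empty:
        logger.info(
            "dropping %d (roi, band) cells with n < %d", len(dropped), min_n
        )
    table = table[table["n"] >= min_n].reset_index(drop=True)
    if table.empty:
        raise ValueError(f"no (roi, band) cell reaches min_n={min_n}; map would be empty")
    # keep band ordering consistent with the scheme
    table["band"] = pd.Categorical(table["band"], categories=bands.names, ordered=True)
    table = table.sort_values(["roi_id", "band"]).reset_index(drop=True)
    table["band"] = table["band"].astype(str)
    provenance = {
        "config_hash": config_hash,
        "subjects": sorted(map(str, rows["subject_id"].unique())),
        "min_n": min_n,
    }
    return NormativeMap(table=table, bands=bands, provenance=provenance)
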