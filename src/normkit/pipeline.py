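"""End-to-end orchestration of the processing stages.

Stages: ``simulate`` (synthetic cohort), ``select`` (interictal segments),
``localise`` (channel tables), ``db`` (document store), ``map`` (normative
map), ``score`` (abnormality maps for held-out subjects).  ``select`` and
``localise`` are independent of each other; the remaining dependencies are
enforced and a missing upstream artifact is rejected naming the stage.

Every run writes a manifest (file SHA-256 digests + config hash + a
step-trace that attributes every input channel to exactly one exclusion
reason or to retention), so identical config + seed reproduce identical
manifests.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from normkit.abnormality import label_resected_regions, score_subject
from normkit.bands import BandScheme
from normkit.db import CohortDB, ValidationError
from normkit.io import read_container
from normkit.normative import (
    NormativeMap,
    PreprocessParams,
    WelchParams,
    aggregate_to_roi,
    band_rbp,
    build_normative_map,
    detect_noisy_channels,
    exclude_pathological,
    loo_outlier_filter,
    metric_config_hash,
    preprocess,
)
from normkit.spatial import (
    MaskVolume,
    ParcellationVolume,
    build_channel_table,
    read_channel_table,
    write_channel_table,
)
from normkit.synth import CohortConfig, generate_cohort
from normkit.temporal import (
    ExamTimeline,
    FlagRules,
    SegmentRecord,
    SelectionPolicy,
    extract_segment,
    flag_unsuitable_channels,
    select_segments,
    suitable_periods,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "select", "localise", "db", "map", "score")

#: upstream stage artifacts each stage requires
_REQUIRES = {
    "simulate": (),
    "select": ("simulate",),
    "localise": ("simulate",),
    "db": ("select", "localise"),
    "map": ("db",),
    "score": ("map",),
}

_ARTIFACTS = {
    "simulate": "cohort",
    "select": "segments",
    "localise": "channels",
    "db": "db",
    "map": "normative_map.csv",
    "score": "abnormality",
}


class PipelineDependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for every decision-point parameter."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    welch: WelchParams = field(default_factory=WelchParams)
    gm_max_dist: float = 5.0
    resect_dist: float = 5.0
    noisy_z: float = 3.0
    #: conservative threshold used in the abnormality path so genuine
    #: spiking is not excluded
    noisy_z_abnormality: float = 5.0
    loo_z: float = 3.0
    min_n: int = 30
    log_level: str = "INFO"

    @property
    def bands(self) -> BandScheme:
        return self.cohort.bands

    @property
    def metric_hash(self) -> str:
        return metric_config_hash(self.preprocess, self.bands, self.welch)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "policy": self.policy.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "welch": self.welch.to_dict(),
            "gm_max_dist": self.gm_max_dist,
            "resect_dist": self.resect_dist,
            "noisy_z": self.noisy_z,
            "noisy_z_abnormality": self.noisy_z_abnormality,
            "loo_z": self.loo_z,
            "min_n": self.min_n,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "policy" in d:
            d["policy"] = SelectionPolicy.from_dict(d["policy"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessParams.from_dict(d["preprocess"])
        if "welch" in d:
            d["welch"] = WelchParams.from_dict(d["welch"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def normative_subjects(self) -> list[str]:
        c = self.cohort
        return [c.subject_id(i) for i in range(c.n_subjects) if not c.is_holdout(i)]

    def holdout_subjects(self) -> list[str]:
        c = self.cohort
        return [c.subject_id(i) for i in range(c.n_subjects) if c.is_holdout(i)]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> None:
    generate_cohort(config.cohort, out / "cohort", policy=config.policy, overwrite=True)


def _stage_select(config: RunConfig, out: Path) -> None:
    cohort_dir = out / "cohort"
    seg_root = out / "segments"
    for i in range(config.cohort.n_subjects):
        sid = config.cohort.subject_id(i)
        sdir = cohort_dir / sid
        timeline = ExamTimeline.from_json(sdir / "timeline.json")
        annotations = json.loads((sdir / "annotations.json").read_text())
        periods = suitable_periods(timeline, config.policy)
        placements = select_segments(periods, config.policy)
        index = json.loads((sdir / "recordings" / "recordings.json").read_text())
        out_dir = seg_root / sid
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, placement in enumerate(placements):
            excerpt = _excerpt_for(index, placement, config.policy.segment_length)
            if excerpt is None:
                logger.warning("%s: no excerpt covers placement %.1f s", sid, placement)
                continue
            rec = read_container(sdir / "recordings" / excerpt["file"])
            seg = extract_segment(
                rec,
                placement,
                config.policy,
                subject_id=sid,
                hospital=config.cohort.hospital,
                segment_number=k + 1,
                exam_start=timeline.exam_start,
                spiking_channel_names=annotations.get("spiking_channels", []),
            )
            flag_unsuitable_channels(seg, FlagRules(power_z_max=config.noisy_z))
            seg.save(out_dir / f"segment{k + 1}.h5")


def _excerpt_for(index: list[dict], placement: float, length: float) -> dict | None:
    for entry in index:
        lo = entry["exam_offset"]
        if lo - 1e-6 <= placement and placement + length <= lo + entry["duration"] + 1e-6:
            return entry
    return None


def _stage_localise(config: RunConfig, out: Path) -> None:
    cohort_dir = out / "cohort"
    parc = ParcellationVolume.from_nifti(cohort_dir / "shared" / "parcellation.nii")
    chan_root = out / "channels"
    chan_root.mkdir(parents=True, exist_ok=True)
    for i in range(config.cohort.n_subjects):
        sid = config.cohort.subject_id(i)
        sdir = cohort_dir / sid
        coords = pd.read_csv(sdir / "coords.csv")
        mask_path = sdir / "resection_mask.nii"
        mask = MaskVolume.from_nifti(mask_path) if mask_path.exists() else None
        annotations = json.loads((sdir / "annotations.json").read_text())
        flags = None
        if annotations.get("spiking_channels"):
            flags = pd.DataFrame(
                {"is_spiking": True},
                index=pd.Index(annotations["spiking_channels"], name="name"),
            )
        table = build_channel_table(
            coords,
            parc,
            mask,
            gm_max_dist=config.gm_max_dist,
            resect_dist=config.resect_dist,
            flags=flags,
        )
        write_channel_table(table, chan_root / f"{sid}.csv")


def _stage_db(config: RunConfig, out: Path) -> None:
    cohort_dir = out / "cohort"
    db = CohortDB(extra_hospitals=(config.cohort.hospital,))
    for i in range(config.cohort.n_subjects):
        sid = config.cohort.subject_id(i)
        db.insert("subject", {"hospital": config.cohort.hospital, "subject_id": sid})
        timeline = ExamTimeline.from_json(cohort_dir / sid / "timeline.json")
        exam_id = f"{sid}-exam1"
        exam_date = timeline.exam_start.split("T")[0]
        db.insert(
            "exam",
            {
                "subject_id": sid,
                "exam_id": exam_id,
                "exam_type": "icEEG",
                "exam_date": exam_date,
                "raw_iceeg_folder_location": str(Path("cohort") / sid / "recordings"),
            },
        )
        table = read_channel_table(out / "channels" / f"{sid}.csv")
        for r in table.to_dict("records"):
            doc = {
                "subject_id": sid,
                "exam_id": exam_id,
                "channel_name": r["name"],
                "hemisphere": r["hemisphere"],
                "electrode_type": r["electrode_type"],
                "location": [r["x"], r["y"], r["z"]],
            }
            if pd.notna(r["roi_id"]):
                doc["roi_ids"] = [int(r["roi_id"])]
                doc["roi_names"] = [r["roi_name"]]
            for flag in ("is_resected", "is_spiking", "is_structurally_abnormal", "is_within_soz"):
                if flag in r and pd.notna(r[flag]):
                    doc[flag] = bool(r[flag])
            db.insert("channel", doc)
        start_dt = timeline.exam_start_datetime
        for seg_path in sorted((out / "segments" / sid).glob("segment*.h5")):
            seg = SegmentRecord.load(seg_path)
            db.insert(
                "iceeg_segment",
                {
                    "subject_id": sid,
                    "exam_id": exam_id,
                    "datetime": seg.start_datetime,
                    "duration": seg.duration,
                    "sampling_frequency": seg.fs,
                    "reference": "referential",
                    "wake_status": seg.wake_status,
                    "file_location": str(seg_path.relative_to(out)),
                    "segment_number": seg.segment_number,
                },
            )
        for sz in timeline.seizures:
            doc = {
                "subject_id": sid,
                "exam_id": exam_id,
                "datetime": (start_dt + _dt.timedelta(seconds=sz.onset)).isoformat(),
                "duration": sz.duration,
                "type": sz.type,
            }
            try:
                db.insert("seizure", doc)
            except ValidationError:
                logger.warning("%s: duplicate seizure datetime skipped", sid)
    db.save(out / "db")


def _subject_metric_rows(
    config: RunConfig,
    out: Path,
    db: CohortDB,
    sid: str,
    *,
    normative: bool,
    trace: dict,
) -> pd.DataFrame:
    """Channel filtering + preprocessing + metric + ROI aggregation for one
    subject; returns long rows (subject_id, roi_id, band, value,
    segment_number)."""
    table = read_channel_table(out / "channels" / f"{sid}.csv")
    all_names = table["name"].tolist()
    if normative:
        retained = exclude_pathological(table)
    else:
        # abnormality path keeps pathological channels, drops only unlocalised
        retained = table.loc[table["roi_id"].notna(), "name"].tolist()
    pathological = [n for n in all_names if n not in retained]
    roi_of = {
        r["name"]: int(r["roi_id"])
        for r in table.to_dict("records")
        if pd.notna(r["roi_id"])
    }
    noisy_z = config.noisy_z if normative else config.noisy_z_abnormality
    segments = db.query_segments({"subject_id": sid})
    rows = []
    strace = {
        "n_channels": len(all_names),
        "pathological": sorted(pathological),
        "segments": {},
    }
    for segdoc in sorted(segments, key=lambda d: d.get("segment_number", 0)):
        seg = SegmentRecord.load(out / segdoc["file_location"])
        unsuitable = [n for n in retained if n in seg.unsuitable_channel_names]
        unlocalised = [n for n in retained if n not in unsuitable and n not in roi_of]
        live = [n for n in retained if n not in unsuitable and n not in unlocalised]
        if len(live) < 3:
            continue
        noisy = detect_noisy_channels(seg.subset(live), z_max=noisy_z)
        final = [n for n in live if n not in noisy]
        if len(final) < 1:
            continue
        strace["segments"][str(seg.segment_number)] = {
            "unsuitable": unsuitable,
            "unlocalised": unlocalised,
            "noisy": noisy,
            "retained": final,
        }
        clean = preprocess(seg.subset(final), config.preprocess)
        rbp = band_rbp(clean, config.bands, config.welch)
        roi_log = aggregate_to_roi(rbp, {n: roi_of[n] for n in final})
        for roi in roi_log.index:
            for band in roi_log.columns:
                rows.append(
                    {
                        "subject_id": sid,
                        "roi_id": int(roi),
                        "band": band,
                        "value": float(roi_log.loc[roi, band]),
                        "segment_number": seg.segment_number,
                    }
                )
    trace[sid] = strace
    return pd.DataFrame(rows)


def _stage_map(config: RunConfig, out: Path, trace: dict) -> None:
    db = CohortDB.load(out / "db")
    frames = []
    for sid in config.normative_subjects():
        rows = _subject_metric_rows(config, out, db, sid, normative=True, trace=trace)
        if not rows.empty:
            frames.append(rows)
    if not frames:
        raise ValueError("no normative subject produced metric rows")
    cohort_rows = pd.concat(frames, ignore_index=True)
    # one segment per subject (lowest surviving number) before outlier logic
    first = cohort_rows.groupby("subject_id")["segment_number"].transform("min")
    cohort_rows = cohort_rows[cohort_rows["segment_number"] == first]
    filtered, removed = loo_outlier_filter(cohort_rows, z_max=config.loo_z)
    trace["loo_removed_rows"] = int(len(removed))
    nmap = build_normative_map(
        filtered,
        bands=config.bands,
        min_n=config.min_n,
        config_hash=config.metric_hash,
    )
    nmap.save(out / "normative_map.csv")


def _stage_score(config: RunConfig, out: Path, trace: dict) -> None:
    db = CohortDB.load(out / "db")
    nmap = NormativeMap.load(out / "normative_map.csv")
    score_dir = out / "abnormality"
    score_dir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for sid in config.holdout_subjects():
        rows = _subject_metric_rows(config, out, db, sid, normative=False, trace=trace)
        if rows.empty:
            logger.warning("%s: no metric rows; skipped", sid)
            continue
        # one segment per subject by construction of pipeline E
        first = rows["segment_number"].min()
        wide = (
            rows[rows["segment_number"] == first]
            .pivot(index="roi_id", columns="band", values="value")[config.bands.names]
        )
        table = read_channel_table(out / "channels" / f"{sid}.csv")
        result = score_subject(
            sid, wide, nmap, channel_table=table, config_hash=config.metric_hash
        )
        report = result.z.copy()
        report.columns = [f"z_{b}" for b in report.columns]
        report["max_abs_z"] = result.abnormality["max_abs_z"]
        report["max_band"] = result.abnormality["band"]
        report["label"] = [result.labels.get(int(r), "") for r in report.index]
        report.to_csv(score_dir / f"{sid}.csv", float_format="%.12g")
        summaries[sid] = result.summary()
    (score_dir / "summary.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: Sequence[str] | str = "all",
) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    The step trace in the manifest attributes every input channel of every
    processed segment to exactly one of: pathological, unsuitable,
    unlocalised, noisy, or retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stages == "all" or stages == ["all"]:
        requested = list(ALL_STAGES)
    else:
        requested = list(stages)
        unknown = set(requested) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in ALL_STAGES if s in requested]

    # ALL_STAGES is already in dependency order, so an included dep always
    # runs before its dependant; otherwise its artifact must already exist
    for stage in ordered:
        for dep in _REQUIRES[stage]:
            if dep in ordered:
                continue
            if not (out / _ARTIFACTS[dep]).exists():
                raise PipelineDependencyError(
                    f"stage {stage!r} requires output of stage {dep!r}; "
                    f"run it first or include it in --stages"
                )

    trace: dict = {}
    for stage in ordered:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            _stage_simulate(config, out)
        elif stage == "select":
            _stage_select(config, out)
        elif stage == "localise":
            _stage_localise(config, out)
        elif stage == "db":
            _stage_db(config, out)
        elif stage == "map":
            _stage_map(config, out, trace)
        elif stage == "score":
            _stage_score(config, out, trace)

    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "config_hash": config.config_hash(),
        "metric_hash": config.metric_hash,
        "stages": ordered,
        "files": files,
        "step_trace": trace,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
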