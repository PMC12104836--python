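"""Whole-cohort generation: files on disk plus a ground-truth record.

The on-disk layout mirrors the recommended per-subject folder structure:

    out/
      cohort_config.json
      ground_truth.json
      shared/parcellation.nii (+ .labels.json)
      SYNH_001/
        timeline.json
        annotations.json          # spiking/artifact channel names
        coords.csv
        resection_mask.nii        # held-out pathological subjects only
        recordings/recordings.json, segment1.h5 ...

Continuous multi-day recordings would be gigabytes per subject, so the
generator emulates the bedside archive as windowed excerpts: it runs the
segment-selection policy on the timeline and writes one short recording
excerpt (segment plus margin) per placement.  Selection downstream
recomputes the placements from the timeline alone and extracts from the
matching excerpt.
"""

from __future__ import annotations

import shutil
from pathlib import Path

import json
import numpy as np
import pandas as pd

from normkit.io import Recording, write_container
from normkit.synth.config import CohortConfig, GroundTruth
from normkit.synth.geometry import generate_geometry, grey_roi_ids
from normkit.synth.signal import generate_signal
from normkit.synth.timeline import generate_timeline
from normkit.temporal import SelectionPolicy, select_segments, suitable_periods

#: seconds of margin around each excerpted placement
EXCERPT_MARGIN = 1.0

_BASE_WEIGHTS = (0.35, 0.25, 0.18, 0.14, 0.08)


def default_roi_profiles(config: CohortConfig) -> dict[int, dict[str, float]]:
    """Deterministic, well-separated band-power profiles per grey ROI.

    Each ROI multiplies a decaying base weight vector by a fixed
    per-ROI jitter pattern, so per-band means differ across ROIs (and are
    recoverable) while every profile keeps a broadly decreasing,
    physiological spectrum.
    """
    bands = list(config.band_edges)
    base = np.asarray(_BASE_WEIGHTS[: len(bands)], dtype=float)
    out: dict[int, dict[str, float]] = {}
    for k, roi in enumerate(grey_roi_ids()):
        jitter = np.random.default_rng([97, k]).normal(0.0, 0.4, size=len(bands))
        w = base * np.exp(jitter)
        w = w / w.sum()
        out[roi] = dict(zip(bands, w))
    return out


def roi_truth_table(config: CohortConfig) -> dict[int, dict[str, dict[str, float]]]:
    """Per (ROI, band) generative mean/SD of log10(RBP)."""
    profiles = (
        {int(k): dict(v) for k, v in config.band_power_profile.items()}
        if config.band_power_profile is not None
        else default_roi_profiles(config)
    )
    truth = {}
    for roi, profile in profiles.items():
        total = sum(profile.values())
        truth[roi] = {
            band: {"mean": float(np.log10(w / total)), "sd": config.roi_sigma}
            for band, w in profile.items()
        }
    return truth


def subject_band_profiles(
    config: CohortConfig, subject_index: int
) -> dict[int, dict[str, float]]:
    """One RBP target profile per ROI for one subject.

    Per-band log10 values are drawn Normal(mean, sd) around the ROI truth;
    held-out subjects get the configured pathological shift applied to the
    first band.  The shift is stated in SDs of the normative log-RBP
    distribution, so the raw boost is solved such that *after*
    renormalisation the band's log10(RBP) moves by exactly
    ``shift * roi_sigma`` (a naive pre-normalisation boost would be
    diluted).  The returned profiles are normalised to sum to 1 per ROI.
    """
    truth = roi_truth_table(config)
    rng = np.random.default_rng([config.seed, subject_index, 3])
    holdout = config.is_holdout(subject_index)
    out: dict[int, dict[str, float]] = {}
    for roi in sorted(truth):
        bands = list(truth[roi])
        logw = np.array(
            [truth[roi][b]["mean"] + truth[roi][b]["sd"] * rng.standard_normal() for b in bands]
        )
        w = 10.0 ** logw
        w = w / w.sum()
        if holdout and roi in config.pathological_rois:
            delta = config.pathological_rois[roi] * config.roi_sigma
            w[0] = _shifted_weight(w[0], delta)
            w[1:] *= (1.0 - w[0]) / w[1:].sum()
        out[roi] = dict(zip(bands, w))
    return out


def _shifted_weight(w: float, delta: float) -> float:
    """New weight for one band of a normalised profile such that its
    log10 relative power increases by ``delta`` after renormalisation."""
    target = w * 10.0 ** delta
    # a share cannot reach 1; clamp just below when the shift is too large
    return min(target, 1.0 - 1e-6)


def sample_cohort_rows(
    config: CohortConfig,
    n_subjects: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[int, dict[str, dict[str, float]]]]:
    """Draw cohort metric rows directly from the generative normals.

    Returns long-format rows (subject_id, roi_id, band, value) where each
    value is exactly Normal(mean, sd) per the returned truth table --
    the signal-free route for testing map construction statistics.
    """
    n = n_subjects if n_subjects is not None else config.n_subjects
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = roi_truth_table(config)
    records = []
    for s in range(n):
        sid = config.subject_id(s)
        for roi in sorted(truth):
            for band, cell in truth[roi].items():
                records.append(
                    {
                        "subject_id": sid,
                        "roi_id": roi,
                        "band": band,
                        "value": cell["mean"] + cell["sd"] * rng.standard_normal(),
                    }
                )
    return pd.DataFrame.from_records(records), truth


def _flagged_channels(config: CohortConfig, subject_index: int, names: list[str]):
    rng = np.random.default_rng([config.seed, subject_index, 5])
    n = len(names)
    n_art = int(round(config.artifact_channel_fraction * n))
    n_spk = int(round(config.spiking_channel_fraction * n))
    picks = rng.permutation(n)
    artifact = sorted(int(i) for i in picks[:n_art])
    spiking = sorted(int(i) for i in picks[n_art : n_art + n_spk])
    return artifact, spiking


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path,
    policy: SelectionPolicy | None = None,
    overwrite: bool = False,
) -> GroundTruth:
    """Write a full synthetic cohort to disk and return its ground truth."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out_dir} is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    policy = policy or SelectionPolicy()

    config.to_json(out_dir / "cohort_config.json")
    parc, _, _, _ = generate_geometry(config, 0)
    shared = out_dir / "shared"
    shared.mkdir()
    parc.to_nifti(shared / "parcellation.nii")

    subjects = []
    for s in range(config.n_subjects):
        sid = config.subject_id(s)
        sdir = out_dir / sid
        sdir.mkdir()

        timeline = generate_timeline(config, s)
        timeline.to_json(sdir / "timeline.json")

        parc_s, coords, mask, true_roi = generate_geometry(config, s)
        coords.to_csv(sdir / "coords.csv", index=False)
        if mask is not None:
            mask.to_nifti(sdir / "resection_mask.nii")

        names = coords["name"].tolist()
        art_idx, spk_idx = _flagged_channels(config, s, names)
        annotations = {
            "artifact_channels": [names[i] for i in art_idx],
            "spiking_channels": [names[i] for i in spk_idx],
        }
        (sdir / "annotations.json").write_text(
            json.dumps(annotations, indent=2, sort_keys=True)
        )

        periods = suitable_periods(timeline, policy)
        placements = select_segments(periods, policy)
        profiles = subject_band_profiles(config, s)
        channel_profiles = [profiles[true_roi[n]] for n in names]
        rdir = sdir / "recordings"
        rdir.mkdir()
        index = []
        for k, placement in enumerate(placements):
            offset = max(placement - EXCERPT_MARGIN, 0.0)
            dur = policy.segment_length + (placement - offset) + EXCERPT_MARGIN
            data = generate_signal(
                channel_profiles,
                duration=dur,
                fs=config.sampling_rate,
                line_noise_hz=config.line_noise_hz,
                seed=int(
                    np.random.default_rng([config.seed, s, 11, k]).integers(2**31)
                ),
                band_edges=config.band_edges,
                osc_strength=config.osc_strength,
                artifact_channels=art_idx,
                spiking_channels=spk_idx,
            )
            fname = f"excerpt{k + 1}.h5"
            write_container(
                rdir / fname,
                Recording(
                    data=data,
                    fs=config.sampling_rate,
                    channel_names=names,
                    start_datetime=timeline.exam_start,
                    exam_offset=offset,
                ),
            )
            index.append({"file": fname, "exam_offset": offset, "duration": dur})
        (rdir / "recordings.json").write_text(
            json.dumps(index, indent=2, sort_keys=True)
        )

        resected = (
            sorted(set(config.pathological_rois) & set(true_roi.values()))
            if (mask is not None)
            else []
        )
        subjects.append(
            {
                "subject_id": sid,
                "is_holdout": config.is_holdout(s),
                "interictal_intervals": [[a, b] for a, b in periods],
                "artifact_channels": annotations["artifact_channels"],
                "spiking_channels": annotations["spiking_channels"],
                "channel_true_roi": true_roi,
                "resected_rois": resected,
            }
        )

    truth = GroundTruth(
        roi_truth=roi_truth_table(config),
        subjects=subjects,
        config=config.to_dict(),
    )
    truth.to_json(out_dir / "ground_truth.json")
    return truth
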