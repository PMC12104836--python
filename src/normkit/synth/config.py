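"""Cohort configuration and ground-truth records."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from normkit.bands import BandScheme, DEFAULT_BAND_EDGES


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``pathological_rois`` maps ROI id to a log-RBP shift expressed in SDs
    of the normative distribution; the shift is applied only to held-out
    subjects (the last ``n_holdout`` of the cohort), which also receive a
    resection mask covering those ROIs.
    """

    n_subjects: int = 10
    n_channels_per_subject: int = 24
    sampling_rate: float = 256.0
    exam_duration: float = 120.0  # hours
    seizure_rate: float = 2.0  # events / day
    seizure_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"focal": 0.5, "subclin": 0.3, "sg": 0.2}
    )
    band_power_profile: Mapping[int, Mapping[str, float]] | None = None
    pathological_rois: Mapping[int, float] = field(default_factory=dict)
    n_holdout: int = 0
    artifact_channel_fraction: float = 0.0
    spiking_channel_fraction: float = 0.0
    line_noise_hz: float = 50.0
    seed: int = 0
    # generative nuisance parameters (placeholders, not cohort estimates)
    roi_sigma: float = 0.1  # SD of per-subject log10 RBP around the ROI mean
    osc_strength: float = 25.0
    hospital: str = "SYNH"
    band_edges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.n_holdout <= self.n_subjects):
            raise ValueError("n_holdout must be within [0, n_subjects]")
        mix_total = sum(self.seizure_type_mix.values())
        if self.seizure_type_mix and abs(mix_total - 1.0) > 1e-9:
            raise ValueError("seizure_type_mix proportions must sum to 1")
        highest = max(high for _, high in self.band_edges.values())
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling_rate must exceed twice the highest band edge ({highest} Hz)"
            )
        if not (0 <= self.artifact_channel_fraction <= 1):
            raise ValueError("artifact_channel_fraction must be a proportion")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def bands(self) -> BandScheme:
        return BandScheme({k: tuple(v) for k, v in self.band_edges.items()})

    def subject_id(self, index: int) -> str:
        """Hospital code + zero-padded 1-based index (e.g. SYNH_001)."""
        return f"{self.hospital}_{index + 1:03d}"

    def is_holdout(self, index: int) -> bool:
        return index >= self.n_subjects - self.n_holdout

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seizure_type_mix"] = dict(self.seizure_type_mix)
        d["pathological_rois"] = {str(k): v for k, v in self.pathological_rois.items()}
        # list-of-triples keeps band order stable under sort_keys serialization
        d["band_edges"] = [[k, lo, hi] for k, (lo, hi) in self.band_edges.items()]
        if self.band_power_profile is not None:
            d["band_power_profile"] = {
                str(k): dict(v) for k, v in self.band_power_profile.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        if d.get("pathological_rois"):
            d["pathological_rois"] = {int(k): float(v) for k, v in d["pathological_rois"].items()}
        if d.get("band_power_profile"):
            d["band_power_profile"] = {
                int(k): dict(v) for k, v in d["band_power_profile"].items()
            }
        if d.get("band_edges"):
            edges = d["band_edges"]
            if isinstance(edges, dict):
                d["band_edges"] = {k: tuple(v) for k, v in edges.items()}
            else:
                d["band_edges"] = {k: (float(lo), float(hi)) for k, lo, hi in edges}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GroundTruth:
    """What the generator actually planted, for oracle checks downstream."""

    #: roi id -> band -> {"mean": mu, "sd": sigma} of log10(RBP)
    roi_truth: dict[int, dict[str, dict[str, float]]]
    #: one record per subject: id, holdout flag, true interictal intervals,
    #: artifact/spiking channel names, channel -> true roi, resected rois
    subjects: list[dict]
    config: dict

    def __post_init__(self) -> None:
        for s in self.subjects:
            known = set(s["channel_true_roi"])
            for name in s["artifact_channels"] + s["spiking_channels"]:
                if name not in known:
                    raise ValueError(f"flagged channel {name!r} not in cohort")
            implanted = set(s["channel_true_roi"].values())
            if not set(s["resected_rois"]) <= implanted:
                raise ValueError("resected ROIs must be implanted ROIs")

    def subject(self, subject_id: str) -> dict:
        for s in self.subjects:
            if s["subject_id"] == subject_id:
                return s
        raise KeyError(subject_id)

    def to_dict(self) -> dict:
        return {
            "roi_truth": {
                str(roi): bands for roi, bands in sorted(self.roi_truth.items())
            },
            "subjects": self.subjects,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            roi_truth={int(k): v for k, v in d["roi_truth"].items()},
            subjects=list(d["subjects"]),
            config=dict(d["config"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))
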