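"""Channel-to-ROI localisation and resection-mask distances.

Channels are assigned to the nearest grey-matter ROI *in the same
hemisphere* by minimising the world-space Euclidean distance between the
channel coordinate and grey voxel centres.  Channels further than a
configurable distance (default 5 mm) from grey matter are left
unassigned ("n/a").  When a binary resection mask is available, the
minimum distance from each channel to the mask defines a resected flag
(default threshold 5 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
TISSUES = ("grey", "white", "other")
ELECTRODE_TYPES = ("grid", "strip", "depth")

#: Columns of the core channel table.
TABLE_COLUMNS = [
    "name", "x", "y", "z", "electrode_type", "hemisphere",
    "roi_id", "roi_name",
]
#: Optional pathology/resection flag columns, in printed order.
FLAG_COLUMNS = [
    "is_resected", "is_spiking", "is_structurally_abnormal", "is_within_soz",
]
#: Distance columns carried alongside the printed columns.
DISTANCE_COLUMNS = ["dist_to_grey", "dist_to_mask"]


@dataclass(frozen=True)
class RoiInfo:
    name: str
    hemisphere: str
    tissue: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES + ("none",):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")


@dataclass
class ParcellationVolume:
    """Integer label volume + affine + label metadata."""

    labels: np.ndarray
    affine: np.ndarray
    label_map: dict[int, RoiInfo]
    _grey_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels missing from label_map: {sorted(missing)}")

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def grey_voxels(self, hemisphere: str):
        """(world coords, labels, voxel indices) of grey voxels in one
        hemisphere, in deterministic lexicographic voxel order (cached)."""
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        if hemisphere not in self._grey_cache:
            grey_ids = {
                lid for lid, info in self.label_map.items()
                if info.tissue == "grey" and info.hemisphere == hemisphere
            }
            mask = np.isin(self.labels, sorted(grey_ids))
            ijk = np.argwhere(mask)  # lexicographic order by construction
            self._grey_cache[hemisphere] = (
                self.voxel_to_world(ijk),
                self.labels[mask],
                ijk,
            )
        return self._grey_cache[hemisphere]

    # -- serialization ------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        """Write a NIfTI volume plus a JSON label-map sidecar."""
        path = Path(path)
        img = nib.Nifti1Image(self.labels.astype(np.int32), self.affine)
        nib.save(img, path)
        sidecar = _labelmap_sidecar(path)
        sidecar.write_text(
            json.dumps(
                {
                    str(lid): [i.name, i.hemisphere, i.tissue]
                    for lid, i in self.label_map.items()
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_nifti(
        cls, path: str | Path, label_map: Mapping[int, RoiInfo] | None = None
    ) -> "ParcellationVolume":
        path = Path(path)
        img = nib.load(path)
        if label_map is None:
            sidecar = _labelmap_sidecar(path)
            raw = json.loads(sidecar.read_text())
            label_map = {
                int(lid): RoiInfo(name, hemi, tissue)
                for lid, (name, hemi, tissue) in raw.items()
            }
        return cls(
            labels=np.asarray(img.dataobj).astype(np.int64),
            affine=img.affine,
            label_map=dict(label_map),
        )


def _labelmap_sidecar(path: Path) -> Path:
    stem = path.name
    for suff in (".nii.gz", ".nii"):
        if stem.endswith(suff):
            stem = stem[: -len(suff)]
            break
    return path.parent / (stem + ".labels.json")


@dataclass
class MaskVolume:
    """Binary volume (e.g. a resection mask) + affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def world_coords(self) -> np.ndarray:
        ijk = np.argwhere(self.data)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "MaskVolume":
        img = nib.load(path)
        return cls(data=np.asarray(img.dataobj) > 0, affine=img.affine)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-9


def nearest_grey_roi(
    xyz,
    parc: ParcellationVolume,
    hemisphere: str,
    max_dist: float = 5.0,
) -> tuple[int | None, float]:
    """Nearest same-hemisphere grey ROI and its distance in mm.

    Returns ``(None, dist)`` when the minimum distance exceeds
    ``max_dist`` (the channel stays unassigned).  Distance ties are broken
    by smallest label id, then lexicographic voxel index.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    coords, labels, _ijk = parc.grey_voxels(hemisphere)
    if len(coords) == 0:
        raise ValueError(f"parcellation has no grey voxels in hemisphere {hemisphere!r}")
    d = np.linalg.norm(coords - np.asarray(xyz, dtype=float), axis=1)
    dmin = d.min()
    tied = np.flatnonzero(d <= dmin + _TIE_TOL)
    # voxels are stored in lexicographic order; among ties pick the smallest
    # label id, then the lexicographically first voxel carrying it
    tied_labels = labels[tied]
    winner = tied[np.flatnonzero(tied_labels == tied_labels.min())[0]]
    roi = int(labels[winner])
    dist = float(dmin)
    if dist > max_dist:
        return None, dist
    return roi, dist


def distance_to_mask(xyz, mask: MaskVolume) -> float:
    """Minimum world-space distance from a point to any mask voxel centre."""
    if mask.n_voxels == 0:
        raise ValueError("resection mask is empty")
    coords = mask.world_coords()
    return float(np.linalg.norm(coords - np.asarray(xyz, dtype=float), axis=1).min())


def build_channel_table(
    coords: pd.DataFrame,
    parc: ParcellationVolume,
    mask: MaskVolume | None = None,
    *,
    gm_max_dist: float = 5.0,
    resect_dist: float = 5.0,
    flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-channel table (one row per channel).

    ``coords`` needs columns name/x/y/z/electrode_type/hemisphere.  When a
    mask is given, ``dist_to_mask`` and ``is_resected`` are computed; when
    ``flags`` (indexed by channel name) provides pathology booleans they
    are passed through.  Absent flags stay absent rather than defaulting
    to false.
    """
    required = {"name", "x", "y", "z", "electrode_type", "hemisphere"}
    missing = required - set(coords.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    if coords["name"].duplicated().any():
        dups = coords.loc[coords["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate channel names: {dups}")
    bad = set(coords["electrode_type"]) - set(ELECTRODE_TYPES)
    if bad:
        raise ValueError(f"unknown electrode types: {sorted(bad)}")

    rows = []
    for r in coords.itertuples(index=False):
        xyz = (float(r.x), float(r.y), float(r.z))
        roi, dist = nearest_grey_roi(xyz, parc, r.hemisphere, max_dist=gm_max_dist)
        row = {
            "name": r.name,
            "x": r.x,
            "y": r.y,
            "z": r.z,
            "electrode_type": r.electrode_type,
            "hemisphere": r.hemisphere,
            "roi_id": roi,
            "roi_name": parc.label_map[roi].name if roi is not None else "n/a",
            "dist_to_grey": dist,
        }
        if mask is not None:
            dmask = distance_to_mask(xyz, mask)
            row["dist_to_mask"] = dmask
            row["is_resected"] = bool(dmask <= resect_dist)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["roi_id"] = table["roi_id"].astype("Int64")
    if flags is not None:
        unknown = set(flags.index) - set(table["name"])
        if unknown:
            raise ValueError(f"flags for unknown channels: {sorted(unknown)}")
        for col in FLAG_COLUMNS:
            if col in flags.columns:
                mapped = table["name"].map(flags[col])
                if col in table.columns:
                    table[col] = mapped.combine_first(table[col])
                else:
                    table[col] = mapped
                table[col] = table[col].astype("boolean")
    order = [c for c in TABLE_COLUMNS + DISTANCE_COLUMNS + FLAG_COLUMNS if c in table.columns]
    return table[order]


def printed_view(table: pd.DataFrame) -> pd.DataFrame:
    """The table restricted to the published column set (no distances)."""
    cols = [c for c in TABLE_COLUMNS + FLAG_COLUMNS if c in table.columns]
    return table[cols]


def write_channel_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    if "roi_id" in out.columns:
        out["roi_id"] = out["roi_id"].astype(object).where(out["roi_id"].notna(), "n/a")
    out.to_csv(path, index=False, na_rep="n/a")


def read_channel_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=["n/a"], keep_default_na=True)
    if "roi_id" in table.columns:
        table["roi_id"] = table["roi_id"].astype("Int64")
    for col in FLAG_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype("boolean")
    return table
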