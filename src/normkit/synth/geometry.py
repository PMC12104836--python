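"""Toy parcellation volumes, channel coordinates and resection masks.

The toy volume is 1 mm isotropic with the left hemisphere at negative
world x.  Grey-matter ROIs are small cubes embedded in hemisphere-filling
white matter; label ids and names reuse the standard FreeSurfer
colour-lookup id space so fixtures carry realistic identifiers
(17 = Left-Hippocampus, etc.).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from normkit.spatial import MaskVolume, ParcellationVolume, RoiInfo
from normkit.synth.config import CohortConfig

#: Subset of the FreeSurfer colour lookup used by the toy volumes.
DK_LOOKUP: dict[int, RoiInfo] = {
    2: RoiInfo("Left-Cerebral-White-Matter", "left", "white"),
    41: RoiInfo("Right-Cerebral-White-Matter", "right", "white"),
    17: RoiInfo("Left-Hippocampus", "left", "grey"),
    18: RoiInfo("Left-Amygdala", "left", "grey"),
    53: RoiInfo("Right-Hippocampus", "right", "grey"),
    54: RoiInfo("Right-Amygdala", "right", "grey"),
    1006: RoiInfo("ctx-lh-entorhinal", "left", "grey"),
    1009: RoiInfo("ctx-lh-inferiortemporal", "left", "grey"),
    1015: RoiInfo("ctx-lh-middletemporal", "left", "grey"),
    1030: RoiInfo("ctx-lh-superiortemporal", "left", "grey"),
    2006: RoiInfo("ctx-rh-entorhinal", "right", "grey"),
    2009: RoiInfo("ctx-rh-inferiortemporal", "right", "grey"),
    2015: RoiInfo("ctx-rh-middletemporal", "right", "grey"),
    2030: RoiInfo("ctx-rh-superiortemporal", "right", "grey"),
}

_SHAPE = (40, 40, 40)
_CUBE = 5
# cube corner slots per hemisphere (voxel coordinates, left; right adds 20 in x)
_SLOTS = [
    (4, 6, 6), (4, 6, 26), (4, 26, 6), (4, 26, 26),
    (12, 6, 6), (12, 26, 26),
]

_LEFT_GREY = [17, 18, 1006, 1009, 1015, 1030]
_RIGHT_GREY = [53, 54, 2006, 2009, 2015, 2030]


def grey_roi_ids() -> list[int]:
    return sorted(_LEFT_GREY + _RIGHT_GREY)


def generate_parcellation(config: CohortConfig | None = None) -> ParcellationVolume:
    """Deterministic toy parcellation (independent of the seed)."""
    labels = np.zeros(_SHAPE, dtype=np.int64)
    labels[:20, :, :] = 2  # left white matter
    labels[20:, :, :] = 41  # right white matter
    for roi, (x, y, z) in zip(_LEFT_GREY, _SLOTS):
        labels[x : x + _CUBE, y : y + _CUBE, z : z + _CUBE] = roi
    for roi, (x, y, z) in zip(_RIGHT_GREY, _SLOTS):
        labels[x + 20 : x + 20 + _CUBE, y : y + _CUBE, z : z + _CUBE] = roi
    affine = np.eye(4)
    affine[:3, 3] = (-20.0, -20.0, -20.0)
    return ParcellationVolume(labels=labels, affine=affine, label_map=dict(DK_LOOKUP))


def generate_geometry(
    config: CohortConfig, subject_index: int
) -> tuple[ParcellationVolume, pd.DataFrame, MaskVolume | None, dict[str, int]]:
    """Channel coordinates (with known true ROI) and optional resection mask.

    Channels are distributed round-robin over the grey ROIs, each placed
    at a random grey voxel centre of its ROI with sub-voxel jitter small
    enough that the voxel remains the channel's nearest grey voxel.  The
    resection mask (held-out subjects with designated pathological ROIs
    only) covers the full cube of every resected ROI.
    """
    parc = generate_parcellation(config)
    rng = np.random.default_rng([config.seed, subject_index, 1])
    rois = grey_roi_ids()
    rows = []
    truth: dict[str, int] = {}
    for i in range(config.n_channels_per_subject):
        roi = rois[i % len(rois)]
        info = parc.label_map[roi]
        voxels = np.argwhere(parc.labels == roi)
        ijk = voxels[rng.integers(len(voxels))]
        xyz = parc.voxel_to_world(ijk)[0] + rng.uniform(-0.4, 0.4, size=3)
        name = f"CH{i + 1:03d}"
        rows.append(
            {
                "name": name,
                "x": round(float(xyz[0]), 3),
                "y": round(float(xyz[1]), 3),
                "z": round(float(xyz[2]), 3),
                "electrode_type": "depth",
                "hemisphere": info.hemisphere,
            }
        )
        truth[name] = roi
    coords = pd.DataFrame(rows)

    mask = None
    resected = sorted(set(config.pathological_rois) & set(truth.values()))
    if resected and config.is_holdout(subject_index):
        data = np.isin(parc.labels, resected)
        mask = MaskVolume(data=data, affine=parc.affine)
    return parc, coords, mask, truth
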