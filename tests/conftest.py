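"""Shared fixtures.

``table1_coords`` / ``table2_flags`` reproduce the published example
channel table for one hippocampal depth electrode (LHIPP1..10); the
``hippocampus_parc`` volume is constructed so localising those printed
coordinates reproduces the printed ROI assignments (17 then 39).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from normkit.spatial import ParcellationVolume, RoiInfo

TABLE1_ROWS = [
    ("LHIPP1", -29.83, -15.10, -9.69, "depth", "left", 17, "Left-Hippocampus"),
    ("LHIPP2", -34.91, -15.10, -8.60, "depth", "left", 17, "Left-Hippocampus"),
    ("LHIPP3", -39.70, -15.10, -7.65, "depth", "left", 17, "Left-Hippocampus"),
    ("LHIPP4", -44.59, -14.44, -6.77, "depth", "left", 39, "lh-middle-temporal"),
    ("LHIPP5", -49.29, -14.44, -5.68, "depth", "left", 39, "lh-middle-temporal"),
    ("LHIPP6", -54.36, -13.71, -4.86, "depth", "left", 39, "lh-middle-temporal"),
    ("LHIPP7", -58.97, -13.71, -4.29, "depth", "left", 39, "lh-middle-temporal"),
    ("LHIPP8", -64.14, -13.24, -3.15, "depth", "left", 39, "lh-middle-temporal"),
    ("LHIPP9", -68.00, -13.24, -2.46, "depth", "left", 39, "lh-middle-temporal"),
    ("LHIPP10", -73.33, -13.24, -1.29, "depth", "left", 39, "lh-middle-temporal"),
]

# columns: resected, spiking, structurally abnormal, within SOZ
TABLE2_FLAGS = {
    "LHIPP1": (False, True, False, True),
    "LHIPP2": (False, True, False, True),
    "LHIPP3": (False, True, False, False),
    "LHIPP4": (False, True, False, False),
    "LHIPP5": (False, True, False, False),
    "LHIPP6": (False, False, False, False),
    "LHIPP7": (False, False, False, False),
    "LHIPP8": (False, False, False, False),
    "LHIPP9": (False, False, False, False),
    "LHIPP10": (False, False, False, False),
}


@pytest.fixture
def table1_coords() -> pd.DataFrame:
    return pd.DataFrame(
        [r[:6] for r in TABLE1_ROWS],
        columns=["name", "x", "y", "z", "electrode_type", "hemisphere"],
    )


@pytest.fixture
def table1_expected() -> pd.DataFrame:
    return pd.DataFrame(
        TABLE1_ROWS,
        columns=[
            "name", "x", "y", "z", "electrode_type", "hemisphere",
            "roi_id", "roi_name",
        ],
    )


@pytest.fixture
def table2_flags() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        TABLE2_FLAGS,
        orient="index",
        columns=["is_resected", "is_spiking", "is_structurally_abnormal", "is_within_soz"],
    ).rename_axis("name")


@pytest.fixture
def hippocampus_parc() -> ParcellationVolume:
    """Left-hemisphere slab where world x in [-40, -25] is ROI 17 and
    [-75, -41] is ROI 39, covering the printed electrode coordinates."""
    shape = (51, 11, 13)
    labels = np.zeros(shape, dtype=np.int64)
    affine = np.eye(4)
    affine[:3, 3] = (-75.0, -20.0, -12.0)
    labels[:35, :, :] = 39  # world x centres -75 .. -41
    labels[35:, :, :] = 17  # world x centres -40 .. -25
    label_map = {
        17: RoiInfo("Left-Hippocampus", "left", "grey"),
        39: RoiInfo("lh-middle-temporal", "left", "grey"),
    }
    return ParcellationVolume(labels=labels, affine=affine, label_map=label_map)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_toy_parcellation(rng: np.random.Generator, shape=(12, 12, 12)) -> ParcellationVolume:
    """A random small parcellation with grey/white labels in both
    hemispheres (voxel x < shape[0]//2 is left)."""
    labels = np.zeros(shape, dtype=np.int64)
    half = shape[0] // 2
    left_grey, right_grey = (17, 18, 1015), (53, 54, 2015)
    labels[:half] = rng.choice((0, 2) + left_grey, size=(half,) + shape[1:])
    labels[half:] = rng.choice((0, 41) + right_grey, size=(shape[0] - half,) + shape[1:])
    label_map = {
        2: RoiInfo("Left-Cerebral-White-Matter", "left", "white"),
        41: RoiInfo("Right-Cerebral-White-Matter", "right", "white"),
        17: RoiInfo("Left-Hippocampus", "left", "grey"),
        18: RoiInfo("Left-Amygdala", "left", "grey"),
        1015: RoiInfo("ctx-lh-middletemporal", "left", "grey"),
        53: RoiInfo("Right-Hippocampus", "right", "grey"),
        54: RoiInfo("Right-Amygdala", "right", "grey"),
        2015: RoiInfo("ctx-rh-middletemporal", "right", "grey"),
    }
    affine = np.eye(4)
    affine[:3, 3] = rng.uniform(-10, 0, size=3).round(1)
    return ParcellationVolume(labels=labels, affine=affine, label_map=label_map)


def brute_force_nearest(parc: ParcellationVolume, xyz, hemisphere: str, max_dist: float):
    """Independent exhaustive scan over every voxel (no vectorised reuse of
    the implementation's cached arrays)."""
    best = None  # (dist, label, (i, j, k))
    nx, ny, nz = parc.labels.shape
    xyz = np.asarray(xyz, dtype=float)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lab = int(parc.labels[i, j, k])
                if lab == 0:
                    continue
                info = parc.label_map[lab]
                if info.tissue != "grey" or info.hemisphere != hemisphere:
                    continue
                world = parc.affine[:3, :3] @ (i, j, k) + parc.affine[:3, 3]
                d = float(np.sqrt(((world - xyz) ** 2).sum()))
                cand = (d, lab, (i, j, k))
                if best is None:
                    best = cand
                elif d < best[0] - 1e-9:
                    best = cand
                elif abs(d - best[0]) <= 1e-9 and (lab, (i, j, k)) < (best[1], best[2]):
                    best = cand
    if best is None:
        raise ValueError("no grey voxel in hemisphere")
    if best[0] > max_dist:
        return None, best[0]
    return best[1], best[0]
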