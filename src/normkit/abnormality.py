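"""Per-subject abnormality maps and resected-vs-spared distinguishability.

A held-out subject's regional log10(RBP) values (computed with the exact
same metric configuration as the normative map) are z-scored against the
map; regional abnormality is the maximum of |z| over bands; regions are
labelled resected when more than 25% of their channels were resected; and
D_RS is the Mann-Whitney AUC separating resected from spared regional
abnormality scores (1 = resected uniformly more abnormal).

The abnormality path deliberately skips pathological-channel exclusion
and regional leave-one-out outlier removal: the abnormalities those steps
would remove are exactly what is being measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: Fraction of a region's channels that must be resected for the region
#: itself to count as resected (strict inequality).
RESECTED_FRACTION = 0.25


class ConfigMismatchError(ValueError):
    """Subject metric and normative map were built with different configs."""


def zscores(
    subject_values: pd.DataFrame,
    nmap,
    config_hash: str | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Z-score a subject's (roi, band) log-RBP against the normative map.

    ``subject_values`` is wide: index roi_id, columns bands.  Returns the
    z table (NaN where the map has no cell) and the list of ROIs absent
    from the map entirely.  Cells with zero normative SD are rejected with
    a diagnostic.
    """
    if config_hash is not None and nmap.config_hash != config_hash:
        raise ConfigMismatchError(
            f"metric config hash {config_hash!r} != map hash {nmap.config_hash!r}; "
            "abnormality scoring requires the identical preprocessing and metric"
        )
    wide = nmap.table.pivot(index="roi_id", columns="band", values="mean_log_rbp")
    sds = nmap.table.pivot(index="roi_id", columns="band", values="sd_log_rbp")
    unscored = sorted(set(subject_values.index) - set(wide.index))
    common = [r for r in subject_values.index if r in wide.index]
    cols = [c for c in subject_values.columns if c in wide.columns]
    zero_sd = sds.loc[common, cols] == 0
    if zero_sd.any().any():
        bad = [
            (int(r), c)
            for r in common
            for c in cols
            if bool(zero_sd.loc[r, c])
        ]
        raise ValueError(f"normative SD is zero for cells {bad}; cannot z-score")
    z = (subject_values.loc[common, cols] - wide.loc[common, cols]) / sds.loc[common, cols]
    z.index.name = "roi_id"
    return z, unscored


def regional_abnormality(z: pd.DataFrame) -> pd.DataFrame:
    """Max |z| over bands per region, with the band attaining it."""
    absz = z.abs()
    if absz.shape[1] < 1:
        raise ValueError("need at least one band column")
    out = pd.DataFrame(
        {
            "max_abs_z": absz.max(axis=1),
            "band": absz.idxmax(axis=1),
        }
    )
    out.index.name = "roi_id"
    return out


def label_resected_regions(channel_table: pd.DataFrame) -> dict[int, str]:
    """Label each implanted region resected/spared from channel flags.

    A region is resected iff strictly more than 25% of its channels carry
    ``is_resected``.  Regions without localised channels are not labelled.
    """
    if "is_resected" not in channel_table.columns:
        raise ValueError("channel table has no is_resected column")
    table = channel_table.dropna(subset=["roi_id"])
    labels: dict[int, str] = {}
    for roi, grp in table.groupby("roi_id"):
        frac = grp["is_resected"].fillna(False).astype(bool).mean()
        labels[int(roi)] = "resected" if frac > RESECTED_FRACTION else "spared"
    return labels


def drs(
    abnormality: Mapping[int, float],
    labels: Mapping[int, str],
    higher_is_resected: bool = True,
) -> float:
    """Distinguishability of resected vs spared regions (Mann-Whitney AUC).

    Computed in closed form from ranks with tie correction:
    ``(#pairs resected > spared + 0.5 * #ties) / (n_R * n_S)``.  With the
    default orientation, 1 means resected regions are uniformly more
    abnormal than spared ones.
    """
    scored = {r: abnormality[r] for r in abnormality if r in labels}
    res = [v for r, v in scored.items() if labels[r] == "resected"]
    spa = [v for r, v in scored.items() if labels[r] == "spared"]
    if not res:
        raise ValueError("no scored region labelled 'resected'; D_RS undefined")
    if not spa:
        raise ValueError("no scored region labelled 'spared'; D_RS undefined")
    values = np.asarray(res + spa, dtype=float)
    ranks = _stats.rankdata(values)  # average ranks handle ties exactly
    n_r, n_s = len(res), len(spa)
    auc = (ranks[:n_r].sum() - n_r * (n_r + 1) / 2) / (n_r * n_s)
    return float(auc if higher_is_resected else 1.0 - auc)


@dataclass
class AbnormalityResult:
    """Scored abnormality map for one subject."""

    subject_id: str
    z: pd.DataFrame  # index roi_id, columns bands
    abnormality: pd.DataFrame  # index roi_id, columns max_abs_z / band
    labels: dict[int, str] = field(default_factory=dict)
    d_rs: float | None = None
    unscored_rois: list[int] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "d_rs": self.d_rs,
            "n_scored_rois": int(len(self.abnormality)),
            "unscored_rois": list(map(int, self.unscored_rois)),
            "labels": {str(k): v for k, v in sorted(self.labels.items())},
        }


def score_subject(
    subject_id: str,
    subject_values: pd.DataFrame,
    nmap,
    channel_table: pd.DataFrame | None = None,
    config_hash: str | None = None,
) -> AbnormalityResult:
    """Full pipeline-E scoring for one subject.

    Z-scores, regional abnormality, and -- when the channel table carries
    resection flags and both classes are present -- D_RS.
    """
    z, unscored = zscores(subject_values, nmap, config_hash=config_hash)
    abn = regional_abnormality(z.dropna(how="all"))
    labels: dict[int, str] = {}
    d = None
    if channel_table is not None and "is_resected" in channel_table.columns:
        labels = label_resected_regions(channel_table)
        scores = {int(r): float(v) for r, v in abn["max_abs_z"].items()}
        have = {labels.get(r) for r in scores if r in labels}
        if "resected" in have and "spared" in have:
            d = drs(scores, labels)
    return AbnormalityResult(
        subject_id=subject_id,
        z=z,
        abnormality=abn,
        labels=labels,
        d_rs=d,
        unscored_rois=unscored,
    )
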