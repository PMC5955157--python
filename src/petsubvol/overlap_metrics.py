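"""Overlap indices between baseline (Ix) and recurrence (R40/R90) sub-volumes.

Five indices on a pair of same-grid binary masks (a = baseline Ix,
b = recurrence R):

* Dice            D   = 2|a n b| / (|a| + |b|)
* Jaccard         J   = |a n b| / |a u b|
* Overlap fraction OF = |a n b| / min(|a|, |b|)
* VcI             = |a n b| / |a|   (common volume over baseline volume)
* VcR             = |a n b| / |b|   (common volume over recurrence volume)

All live in [0, 1] with J <= D <= OF and D = 2J/(1+J).  Concordance is
graded on a Cohen-kappa-style scale (very low ... very good in 0.2 steps).
Cohort aggregation mirrors the usual reporting: per-threshold index means
and SDs, and counts of patients with any Ix n R overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image_io import BinaryMask
from .segmentation import MetabolicSubVolume

__all__ = [
    "OverlapResult",
    "ConcordanceCategory",
    "overlap_indices",
    "classify_concordance",
    "cohort_overlap_table",
    "overlap_presence_counts",
    "INDEX_NAMES",
    "BASELINE_LABELS",
]

INDEX_NAMES = ("dice", "jaccard", "of", "vci", "vcr")
BASELINE_LABELS = ("I30", "I40", "I50", "I60", "I70", "I80", "I90")


class ConcordanceCategory(Enum):
    VERY_LOW = "very low"
    LOW = "low"
    MODERATE = "moderate"
    GOOD = "good"
    VERY_GOOD = "very good"


@dataclass(frozen=True)
class OverlapResult:
    dice: float
    jaccard: float
    of: float
    vci: float
    vcr: float
    intersection_cc: float
    label_i: str = "I"
    label_r: str = "R"

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def _mask_of(x: BinaryMask | MetabolicSubVolume) -> BinaryMask:
    return x.mask if isinstance(x, MetabolicSubVolume) else x


def overlap_indices(
    a: BinaryMask | MetabolicSubVolume,
    b: BinaryMask | MetabolicSubVolume,
    label_i: str = "I",
    label_r: str = "R",
) -> OverlapResult:
    """The five overlap indices for a (baseline, recurrence) mask pair.

    Both masks must be nonempty and share one grid; indices are voxel-count
    ratios (equivalently volume ratios on a common grid).
    """
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.grid != mb.grid:
        raise ValueError("overlap requires masks on the same grid")
    na, nb = ma.voxel_count, mb.voxel_count
    if na == 0 or nb == 0:
        raise ValueError("overlap indices are undefined for an empty mask")
    inter = int(np.count_nonzero(ma.membership & mb.membership))
    union = na + nb - inter
    return OverlapResult(
        dice=2.0 * inter / (na + nb),
        jaccard=inter / union,
        of=inter / min(na, nb),
        vci=inter / na,
        vcr=inter / nb,
        intersection_cc=inter * ma.grid.voxel_volume_cc,
        label_i=label_i,
        label_r=label_r,
    )


def classify_concordance(value: float) -> ConcordanceCategory:
    """Grade an overlap value on the five-step concordance scale.

    Half-open bins [0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 0.8], (0.8, 1]
    (the upper edge belongs to the lower category), a total classification
    of [0, 1].
    """
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"concordance value must be in [0, 1], got {value}")
    if value <= 0.2:
        return ConcordanceCategory.VERY_LOW
    if value <= 0.4:
        return ConcordanceCategory.LOW
    if value <= 0.6:
        return ConcordanceCategory.MODERATE
    if value <= 0.8:
        return ConcordanceCategory.GOOD
    return ConcordanceCategory.VERY_GOOD


SubVolumeSet = Mapping[str, BinaryMask | MetabolicSubVolume]


def cohort_overlap_table(
    records: Sequence[SubVolumeSet],
    r_label: str = "R40",
    baseline_labels: Sequence[str] = BASELINE_LABELS,
) -> pd.DataFrame:
    """Cohort mean +/- SD of each index, per baseline threshold, against one R mask.

    One row per Ix label, columns ``<index>_mean`` / ``<index>_sd`` (population
    SD, ddof=0 so a single-patient cohort reports SD 0).  Patients with zero
    overlap contribute their zeros to the means; the ``zero_overlap_included``
    attribute records this choice.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    rows = []
    for lab in baseline_labels:
        per_index = {k: [] for k in INDEX_NAMES}
        for rec in records:
            res = overlap_indices(rec[lab], rec[r_label], label_i=lab, label_r=r_label)
            for k in INDEX_NAMES:
                per_index[k].append(getattr(res, k))
        row: dict[str, float | str] = {"threshold": lab}
        for k in INDEX_NAMES:
            v = np.asarray(per_index[k])
            row[f"{k}_mean"] = float(v.mean())
            row[f"{k}_sd"] = float(v.std(ddof=0))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("threshold")
    df.attrs["r_label"] = r_label
    df.attrs["zero_overlap_included"] = True
    return df


def overlap_presence_counts(
    records: Sequence[SubVolumeSet],
    r_label: str = "R90",
    baseline_labels: Sequence[str] = BASELINE_LABELS,
    min_voxels: int = 1,
) -> pd.DataFrame:
    """Count of patients whose Ix intersects the R mask, per threshold.

    "Overlap present" means at least ``min_voxels`` shared voxels (default 1).
    Returns one row per Ix with columns n_overlap, n_total and percent
    (rounded to integer).  Counts are monotone non-increasing in x because
    the Ix masks are nested.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    n_total = len(records)
    rows = []
    for lab in baseline_labels:
        n_overlap = 0
        for rec in records:
            ma = _mask_of(rec[lab]).membership
            mb = _mask_of(rec[r_label]).membership
            if int(np.count_nonzero(ma & mb)) >= min_voxels:
                n_overlap += 1
        rows.append(
            {
                "threshold": lab,
                "n_overlap": n_overlap,
                "n_total": n_total,
                "percent": int(round(100.0 * n_overlap / n_total)),
            }
        )
    df = pd.DataFrame(rows).set_index("threshold")
    df.attrs["r_label"] = r_label
    df.attrs["min_voxels"] = min_voxels
    return df
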