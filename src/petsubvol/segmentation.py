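"""Fixed-percentage-of-SUVmax delineation of metabolic tumor sub-volumes.

A sub-volume at threshold fraction f is the 26-connected component, seeded
at the SUVmax voxel, of all voxels inside the operator's VOI whose SUV is
>= f * SUVmax.  Baseline scans use the seven fractions 0.30 ... 0.90
(labels I30 ... I90); follow-up scans use 0.40 and 0.90 (labels R40, R90).
Because every fraction shares the same seed voxel and reference SUVmax,
the series is exactly nested: mask(f2) is a subset of mask(f1) for f1 < f2.

Scalars: MTV (cm^3) = voxel count x voxel volume; SUVmean over the mask;
TLG = MTV x SUVmean, defined for the 40% mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, SuvImage, WorldBox

__all__ = [
    "Voi",
    "MetabolicSubVolume",
    "BASELINE_FRACTIONS",
    "FOLLOWUP_FRACTIONS",
    "find_suvmax",
    "delineate",
    "delineate_series",
    "tlg",
]

#: Lesion bounding box in world mm (operator VOI).
Voi = WorldBox

#: The seven baseline threshold fractions and the two follow-up ones.
BASELINE_FRACTIONS: tuple[float, ...] = (0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)
FOLLOWUP_FRACTIONS: tuple[float, ...] = (0.40, 0.90)

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MetabolicSubVolume:
    """A delineated sub-volume with its derived scalars."""

    mask: BinaryMask
    label: str
    threshold_fraction: float
    suvmax: float
    suv_mean: float
    mtv_cc: float
    tlg: float | None = None  # MTV x SUVmean; populated for 40% masks

    @property
    def voxel_count(self) -> int:
        return self.mask.voxel_count


def find_suvmax(image: SuvImage, voi: Voi) -> tuple[float, tuple[int, int, int]]:
    """Maximum SUV inside the VOI and its voxel index.

    Ties are broken by the smallest C-order linear index of the full array.
    """
    sl = voi.index_slices(image.grid)
    sub = image.values[sl]
    if sub.size == 0:
        raise ValueError("VOI contains no voxels")
    local = np.unravel_index(int(np.argmax(sub)), sub.shape)
    idx = tuple(int(s.start + l) for s, l in zip(sl, local))
    return float(image.values[idx]), idx


def delineate(
    image: SuvImage, voi: Voi, fraction: float, label: str | None = None
) -> MetabolicSubVolume:
    """Delineate one sub-volume at ``fraction`` x SUVmax within the VOI.

    The mask is the 26-connected component containing the SUVmax voxel of
    the super-threshold set (>= comparison, so ties at the threshold are
    members and fraction 1.0 is nonempty).  Scalars are computed on the
    un-interpolated image.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    suvmax, seed = find_suvmax(image, voi)
    sl = voi.index_slices(image.grid)
    sub = image.values[sl]
    super_thr = sub >= fraction * suvmax
    labels, _ = ndimage.label(super_thr, structure=_CONNECTIVITY_26)
    seed_local = tuple(s - sl_.start for s, sl_ in zip(seed, sl))
    comp = labels == labels[seed_local]

    membership = np.zeros(image.grid.shape, dtype=bool)
    membership[sl] = comp
    mask = BinaryMask(image.grid, membership)

    n = mask.voxel_count
    suv_mean = float(image.values[membership].mean()) if n else 0.0
    mtv_cc = n * image.grid.voxel_volume_cc
    if label is None:
        label = f"I{round(fraction * 100):d}"
    out = MetabolicSubVolume(
        mask=mask, label=label, threshold_fraction=float(fraction),
        suvmax=suvmax, suv_mean=suv_mean, mtv_cc=mtv_cc,
    )
    if abs(fraction - 0.40) < 1e-9:
        out.tlg = mtv_cc * suv_mean
    return out


def delineate_series(
    image: SuvImage,
    voi: Voi,
    fractions: Sequence[float] = BASELINE_FRACTIONS,
    label_prefix: str = "I",
) -> dict[str, MetabolicSubVolume]:
    """Delineate one sub-volume per fraction (default I30 ... I90).

    All fractions share the same VOI, hence the same SUVmax and seed voxel,
    so the returned masks are nested: higher fractions are subsets.
    """
    out: dict[str, MetabolicSubVolume] = {}
    for f in fractions:
        label = f"{label_prefix}{round(f * 100):d}"
        out[label] = delineate(image, voi, f, label=label)
    return out


def tlg(image: SuvImage, mask40: MetabolicSubVolume) -> float:
    """Total lesion glycolysis: MTV(40%) x SUVmean over that mask (SUV x cm^3)."""
    if abs(mask40.threshold_fraction - 0.40) > 1e-9:
        raise ValueError(
            f"TLG is defined on the 40% mask, got fraction {mask40.threshold_fraction}"
        )
    n = mask40.mask.voxel_count
    if n == 0:
        return 0.0
    suv_mean = float(image.values[mask40.mask.membership].mean())
    return mask40.mask.volume_cc * suv_mean
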