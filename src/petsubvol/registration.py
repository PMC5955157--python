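"""Rigid mutual-information registration of sequential PET/CT scan pairs.

The follow-up scan is aligned to the baseline scan, which always serves as
the reference: the anatomical (CT-like) volumes drive a 6-DOF rigid fit by
mutual-information maximization inside a region of interest derived from the
baseline PET high-uptake area, and the resulting transform is then applied
to the follow-up PET.

Transform convention
--------------------
``RigidTransform`` maps *baseline (reference) world points into follow-up
world coordinates* — the resampling (pull-back) convention: to express the
follow-up image on the baseline grid, each baseline voxel center is pushed
through the transform and the follow-up image is interpolated there.  Its
inverse is the physical repositioning map carrying follow-up space onto
baseline space.  Rotations use Euler order Z-Y-X (``R = Rz @ Ry @ Rx``),
in degrees, about an explicit center (by default the fixed-image center).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .image_io import BinaryMask, SuvImage, VolumeGrid, WorldBox

__all__ = [
    "RigidTransform",
    "RegistrationRegion",
    "RegistrationOptions",
    "RegistrationResult",
    "derive_region",
    "mutual_information",
    "register_rigid",
    "apply_rigid",
]

#: Region of interest for registration: an axis-aligned box in baseline world mm.
RegistrationRegion = WorldBox


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map p -> R (p - c) + c + t with Euler Z-Y-X rotation (degrees)."""

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("translation_mm", "rotation_deg", "center_mm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a triple")
            object.__setattr__(self, name, tuple(v))

    @property
    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation_deg
        # extrinsic x-y-z application order == Rz @ Ry @ Rx
        return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()

    @property
    def offset_mm(self) -> np.ndarray:
        """o such that p -> R p + o."""
        c = np.asarray(self.center_mm)
        return c + np.asarray(self.translation_mm) - self.rotation_matrix @ c

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of world points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation_matrix.T + self.offset_mm

    def inverse(self) -> "RigidTransform":
        R_inv = self.rotation_matrix.T
        o_inv = -R_inv @ self.offset_mm
        rx, ry, rz = Rotation.from_matrix(R_inv).as_euler("xyz", degrees=True)
        c = np.asarray(self.center_mm)
        t_inv = o_inv - c + R_inv @ c
        return RigidTransform(tuple(t_inv), (float(rx), float(ry), float(rz)), tuple(c))

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.translation_mm, 0, atol=1e-12)
            and np.allclose(self.rotation_deg, 0, atol=1e-12)
        )

    def to_dict(self) -> dict:
        return {
            "translation_mm": list(self.translation_mm),
            "rotation_deg": list(self.rotation_deg),
            "center_mm": list(self.center_mm),
            "convention": "reference-to-followup; Euler ZYX (R = Rz@Ry@Rx), degrees, about center_mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["translation_mm"]), tuple(d["rotation_deg"]), tuple(d["center_mm"]))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RegistrationOptions:
    """Knobs of the MI optimizer (all deterministic)."""

    bins: int = 32
    percentile_clip: tuple[float, float] = (1.0, 99.0)
    coarse_factor: int = 2          # downsampling of the first multiresolution level
    coarse_smooth_voxels: float = 1.0
    # mild smoothing at full resolution: suppresses the interpolation-induced
    # MI bias toward fractional-voxel offsets on noisy images
    fine_smooth_voxels: float = 0.7
    max_translation_mm: float = 40.0
    optimize_rotation: bool = True
    xtol_coarse: float = 0.05
    xtol_fine: float = 0.01
    maxiter: int = 60


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_mi: float
    converged: bool
    n_evaluations: int


def derive_region(
    baseline_pet: SuvImage, fraction: float = 0.30, margin_mm: float = 40.0
) -> RegistrationRegion:
    """High-uptake bounding box of the baseline PET, dilated by a margin.

    The box spans all voxels with SUV >= fraction * SUVmax, expanded by
    ``margin_mm`` on every side and clipped to the image domain.
    """
    vals = baseline_pet.values
    vmax = float(vals.max())
    if vmax <= 0:
        raise ValueError("PET image has no positive voxel; cannot derive a region")
    sel = np.argwhere(vals >= fraction * vmax)
    if sel.size == 0:
        raise ValueError("empty super-threshold set")
    lo = baseline_pet.grid.index_to_world(sel.min(axis=0))
    hi = baseline_pet.grid.index_to_world(sel.max(axis=0))
    return WorldBox(tuple(lo), tuple(hi)).expand(margin_mm).clip_to(baseline_pet.grid)


def _joint_histogram_mi(a: np.ndarray, b: np.ndarray, bins: int,
                        a_edges: np.ndarray | None = None,
                        b_edges: np.ndarray | None = None,
                        clip: tuple[float, float] = (1.0, 99.0)) -> float:
    if a_edges is None:
        a_edges = _hist_edges(a, bins, clip)
    if b_edges is None:
        b_edges = _hist_edges(b, bins, clip)
    h, _, _ = np.histogram2d(np.clip(a, a_edges[0], a_edges[-1]),
                             np.clip(b, b_edges[0], b_edges[-1]),
                             bins=[a_edges, b_edges])
    n = h.sum()
    if n == 0:
        return 0.0
    p = h / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def _soft_joint_mi(a_idx: np.ndarray, bins: int, b: np.ndarray, b_edges: np.ndarray) -> float:
    """MI with linear partial-volume binning of ``b`` (continuous in b).

    The fixed image is hard-binned once (``a_idx``); each moving sample
    spreads linearly over its two neighboring bins, so the objective varies
    smoothly with the transform parameters instead of jumping at bin edges.
    """
    step = b_edges[1] - b_edges[0]
    u = np.clip((b - b_edges[0]) / step, 0.0, bins - 1.0)
    j0 = np.minimum(u.astype(np.intp), bins - 2)
    frac = u - j0
    flat = a_idx * bins + j0
    h = np.bincount(flat, weights=1.0 - frac, minlength=bins * bins) + np.bincount(
        flat + 1, weights=frac, minlength=bins * bins
    )
    p = h.reshape(bins, bins) / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return max(float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz]))), 0.0)


def _hist_edges(values: np.ndarray, bins: int, clip: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(values, clip)
    if hi <= lo:
        hi = lo + 1e-6
    return np.linspace(lo, hi, bins + 1)


def mutual_information(
    fixed: SuvImage, moving: SuvImage, region: RegistrationRegion | None = None, bins: int = 32
) -> float:
    """Mutual information (nats) of two same-grid images inside a region.

    Estimated from a bins x bins joint histogram of paired voxels, with each
    image's histogram range clipped to its 1st-99th percentile inside the
    region.  Warns when the region holds fewer than bins^2/4 voxels (the
    histogram is then too sparse for a stable estimate).
    """
    if fixed.grid != moving.grid:
        raise ValueError("mutual_information requires images on the same grid")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if region is None:
        sl = tuple(slice(None) for _ in range(3))
    else:
        sl = region.index_slices(fixed.grid)
    a = fixed.values[sl].ravel()
    b = moving.values[sl].ravel()
    if a.size < bins * bins / 4:
        warnings.warn(
            f"region has {a.size} voxels < bins^2/4 = {bins * bins / 4:.0f}: MI estimate unstable",
            stacklevel=2,
        )
    return _joint_histogram_mi(a, b, bins)


def _resample_points(image: SuvImage, points: np.ndarray, order: int, fill: float) -> np.ndarray:
    """Interpolate image values at (N, 3) world points."""
    idx = image.grid.world_to_index(points)
    return ndimage.map_coordinates(
        image.values, idx.T, order=order, mode="constant", cval=fill, prefilter=False
    )


def _intensity_com(image: SuvImage) -> np.ndarray:
    v = image.values.astype(float)
    v = np.maximum(v - v.mean(), 0.0)
    if v.sum() <= 0:
        return image.grid.center_mm
    com_idx = np.array(ndimage.center_of_mass(v))
    return image.grid.index_to_world(com_idx)


def register_rigid(
    fixed_anat: SuvImage,
    moving_anat: SuvImage,
    region: RegistrationRegion | None = None,
    opts: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Estimate the 6-DOF rigid transform aligning ``moving_anat`` to ``fixed_anat``.

    Two-level multiresolution (smoothed/downsampled, then full resolution)
    derivative-free Powell search maximizing the joint-histogram MI inside
    ``region`` (whole fixed domain if None).  Translation is initialized from
    the intensity centers of mass.  Deterministic given inputs and options.
    Non-convergence is flagged on the result, never raised.
    """
    opts = opts or RegistrationOptions()
    if region is None:
        region = fixed_anat.grid.domain_box()
    center = tuple(fixed_anat.grid.center_mm)

    sl = region.index_slices(fixed_anat.grid)
    crop = fixed_anat.values[sl]
    crop_origin = fixed_anat.grid.index_to_world([s.start for s in sl])
    spacing = np.asarray(fixed_anat.grid.spacing)

    t0 = _intensity_com(moving_anat) - _intensity_com(fixed_anat)
    t0 = np.clip(t0, -opts.max_translation_mm, opts.max_translation_mm)
    params = np.array([*t0, 0.0, 0.0, 0.0])
    n_eval = 0
    success = True

    levels = [
        (opts.coarse_factor, opts.coarse_smooth_voxels, opts.xtol_coarse),
        (1, opts.fine_smooth_voxels, opts.xtol_fine),
    ]
    for factor, smooth, xtol in levels:
        if smooth > 0:
            fixed_lvl = ndimage.gaussian_filter(crop, smooth)
            moving_lvl_values = ndimage.gaussian_filter(moving_anat.values, smooth)
        else:
            fixed_lvl = crop
            moving_lvl_values = moving_anat.values
        moving_lvl = SuvImage(moving_anat.grid, np.maximum(moving_lvl_values, 0), moving_anat.modality)
        sub = tuple(slice(None, None, factor) for _ in range(3))
        fixed_sub = fixed_lvl[sub]
        # world coordinates of the level's fixed samples
        idx = np.moveaxis(np.indices(fixed_sub.shape), 0, -1).reshape(-1, 3) * factor
        pts = idx * spacing + crop_origin
        a = fixed_sub.ravel()
        a_edges = _hist_edges(a, opts.bins, opts.percentile_clip)
        b_edges = _hist_edges(moving_lvl.values, opts.bins, opts.percentile_clip)
        a_idx = np.clip(np.searchsorted(a_edges, a, side="right") - 1, 0, opts.bins - 1)

        def objective(p: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            rot = tuple(p[3:6]) if opts.optimize_rotation else (0.0, 0.0, 0.0)
            tr = RigidTransform(tuple(p[:3]), rot, center)
            b = _resample_points(moving_lvl, tr.apply(pts), order=1, fill=0.0)
            return -_soft_joint_mi(a_idx, opts.bins, b, b_edges)

        x0 = params if opts.optimize_rotation else params[:3]
        res = optimize.minimize(
            lambda p: objective(np.concatenate([p, np.zeros(3)]) if p.size == 3 else p),
            x0,
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-6, "maxiter": opts.maxiter},
        )
        success = success and bool(res.success)
        params = np.concatenate([res.x, np.zeros(3)]) if res.x.size == 3 else np.asarray(res.x)

    rot = tuple(params[3:6]) if opts.optimize_rotation else (0.0, 0.0, 0.0)
    transform = RigidTransform(tuple(params[:3]), rot, center)
    final_mi = -res.fun
    return RegistrationResult(transform=transform, final_mi=float(final_mi),
                              converged=success, n_evaluations=n_eval)


def apply_rigid(
    image: SuvImage | BinaryMask,
    transform: RigidTransform,
    target_grid: VolumeGrid | None = None,
    interpolation: str = "TRILINEAR",
) -> SuvImage | BinaryMask:
    """Resample an image onto ``target_grid`` by pulling values through the transform.

    Each target voxel center x receives the input value interpolated at
    transform(x); points falling outside the input domain get 0.  Masks are
    always resampled nearest-neighbor (binarity preserved); images use
    trilinear unless ``interpolation='NEAREST'``.
    """
    is_mask = isinstance(image, BinaryMask)
    src_grid = image.grid
    if target_grid is None:
        target_grid = src_grid
    order = 0 if (is_mask or interpolation.upper() == "NEAREST") else 1
    if interpolation.upper() not in ("NEAREST", "TRILINEAR"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    values = image.membership.astype(np.float32) if is_mask else image.values
    R = transform.rotation_matrix
    sp_s = np.asarray(src_grid.spacing)
    sp_t = np.asarray(target_grid.spacing)
    # input_index = A @ output_index + o  (scipy affine_transform convention)
    A = (R * sp_t[np.newaxis, :]) / sp_s[:, np.newaxis]
    o = (R @ np.asarray(target_grid.origin) + transform.offset_mm - np.asarray(src_grid.origin)) / sp_s
    out = ndimage.affine_transform(
        values, A, offset=o, output_shape=target_grid.shape,
        order=order, mode="constant", cval=0.0, prefilter=False,
    )
    if is_mask:
        return BinaryMask(target_grid, out > 0.5)
    out = np.maximum(out, 0.0) if image.modality == "PET" else out
    return SuvImage(target_grid, out.astype(np.float32), image.modality)
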