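"""Seeded synthetic PET/CT phantom pairs with known ground truth.

Each phantom patient is a continuous scene defined in *baseline* world
coordinates: a body ellipsoid with uniform background FDG uptake, a set of
high-intensity anatomical landmark structures (registration anchors), and
— on PET — a heterogeneous tumor built from generalized-Gaussian uptake
kernels ``amp * exp(-r^p)`` confined to a tumor ellipsoid and rescaled so
the noise-free grid maximum equals the target SUVmax.  The baseline scan
samples the scene at voxel centers; the follow-up scan observes the *same
scene coordinates* through the inverse of a known rigid repositioning
transform (exact analytic resampling, so the true transform is available
as registration ground truth), with the tumor replaced by a recurrence
lesion (LRRD patients) or by plain background (complete responders).
i.i.d. Gaussian noise is added last; PET is clipped at zero.

Scale calibration (frozen):

* Kernel sharpness p = 1.8 (baseline) and p = 1.4 (recurrence) reproduce
  the clinical sub-volume ratios I90/I40 ~ 0.025 and R90/R40 ~ 0.008 of
  the threshold series analytically.
* Cohort MTV(40%) targets are lognormal with medians 8.9 cc (complete
  response) and 8.9 x 2.64 = 23.5 cc (local recurrence/residual disease),
  log-SD 0.45; group SUVmax ~ N(13.2, 3.1^2) and N(16.1, 5.2^2) truncated
  above 5.  Recurrence lesions are placed *edge-weighted*: their centroid
  sits at a random fraction (default 0.35-0.80) of the distance from the
  tumor centroid to the tumor boundary, emulating relapse at the rim of
  the baseline uptake distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import BinaryMask, SuvImage, VolumeGrid
from .registration import RigidTransform

__all__ = [
    "UptakeKernel",
    "LesionSpec",
    "AnatomySpec",
    "PhantomConfig",
    "PatientPhantom",
    "CohortParams",
    "default_grid",
    "baseline_kernels",
    "recurrence_kernels",
    "lesion_from_target_volume",
    "shifted_copy",
    "default_patient_config",
    "generate_patient",
    "generate_cohort_configs",
    "generate_cohort",
    "sample_mtv40",
]


@dataclass(frozen=True)
class UptakeKernel:
    """One intra-tumor uptake focus, in normalized lesion coordinates.

    ``center_frac`` is the kernel center as a fraction of the lesion
    semi-axes; per-axis widths are ``sigma_frac * semi_axes`` (anisotropic,
    following the lesion shape).  ``sharpness`` is the exponent p of the
    generalized-Gaussian profile exp(-r^p): lower p gives a sharper peak
    with heavier shoulders (a smaller 90%-isocontour for the same 40% one).
    """

    center_frac: tuple[float, float, float]
    sigma_frac: float
    amplitude: float
    sharpness: float


def baseline_kernels(sharpness: float = 1.8) -> tuple[UptakeKernel, ...]:
    """Default 3-kernel heterogeneous baseline uptake (one dominant focus)."""
    return (
        UptakeKernel((0.32, 0.16, -0.10), 0.55, 1.00, sharpness),
        UptakeKernel((-0.45, 0.30, 0.20), 0.28, 0.55, sharpness),
        UptakeKernel((0.10, -0.52, 0.35), 0.25, 0.50, sharpness),
    )


def recurrence_kernels(sharpness: float = 1.4) -> tuple[UptakeKernel, ...]:
    """Default recurrence uptake: a sharp dominant focus plus one satellite."""
    return (
        UptakeKernel((0.12, 0.0, -0.05), 0.55, 1.00, sharpness),
        UptakeKernel((-0.40, 0.30, 0.10), 0.25, 0.45, sharpness),
    )


@dataclass(frozen=True)
class LesionSpec:
    """A tumor or recurrence lesion: ellipsoid support + uptake kernels + SUVmax."""

    centroid_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    suvmax: float
    kernels: tuple[UptakeKernel, ...]

    def __post_init__(self) -> None:
        if any(not (s > 0) for s in self.semi_axes_mm):
            raise ValueError(f"lesion semi-axes must be positive, got {self.semi_axes_mm}")

    def boundary_distance(self, direction: np.ndarray) -> float:
        """Distance from centroid to the ellipsoid surface along a unit direction."""
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        return 1.0 / math.sqrt(float(np.sum((u / np.asarray(self.semi_axes_mm)) ** 2)))


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    intensity: float


@dataclass(frozen=True)
class TissueBlob:
    """Broad Gaussian soft-tissue density variation (registration texture)."""

    center_mm: tuple[float, float, float]
    sigma_mm: float
    amplitude: float


@dataclass(frozen=True)
class AnatomySpec:
    """CT-like scene: body ellipsoid, soft-tissue density texture, landmark spheres.

    The tissue blobs give the anatomy an intensity gradient everywhere, as
    real CT soft tissue does; without them a uniform body would leave the
    mutual-information surface nearly flat away from the few landmarks.
    """

    body_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_semi_axes_mm: tuple[float, float, float] = (95.0, 85.0, 115.0)
    body_intensity: float = 1.0
    outside_intensity: float = 0.0
    landmarks: tuple[Sphere, ...] = (
        Sphere((50.0, -10.0, -50.0), 9.0, 3.0),
        Sphere((-40.0, 45.0, 30.0), 8.0, 2.8),
        Sphere((10.0, -50.0, 45.0), 8.0, 3.2),
        Sphere((45.0, 50.0, -20.0), 7.0, 2.6),
    )
    tissue_blobs: tuple[TissueBlob, ...] = (
        TissueBlob((30.0, -30.0, 20.0), 30.0, 0.30),
        TissueBlob((-45.0, 10.0, -40.0), 26.0, -0.25),
        TissueBlob((0.0, 50.0, 55.0), 34.0, 0.22),
        TissueBlob((55.0, 35.0, 40.0), 24.0, -0.28),
        TissueBlob((-20.0, -50.0, -60.0), 28.0, 0.26),
        TissueBlob((-55.0, -25.0, 50.0), 30.0, -0.20),
        TissueBlob((20.0, 15.0, -75.0), 32.0, 0.24),
        TissueBlob((-10.0, 60.0, -25.0), 26.0, -0.22),
    )


def default_grid() -> VolumeGrid:
    """64^3 voxels at 4 mm isotropic, centered on the world origin."""
    return VolumeGrid(shape=(64, 64, 64), spacing=(4.0, 4.0, 4.0), origin=(-126.0, -126.0, -126.0))


@dataclass(frozen=True)
class PhantomConfig:
    """Full recipe for one phantom patient (deterministic given ``seed``)."""

    tumor: LesionSpec
    recurrence: LesionSpec | None = None
    grid: VolumeGrid = field(default_factory=default_grid)
    anatomy: AnatomySpec = field(default_factory=AnatomySpec)
    background_suv: float = 1.5
    outside_suv: float = 0.1
    noise_sd: float = 0.1
    true_transform: RigidTransform = field(default_factory=RigidTransform)
    seed: int = 0
    group: str | None = None  # "CR" | "LRRD"; inferred from recurrence if None

    def resolved_group(self) -> str:
        if self.group is not None:
            return self.group
        return "LRRD" if self.recurrence is not None else "CR"

    def validate(self) -> None:
        margin = 4.0
        dom = self.grid.domain_box()
        for name, lesion in (("tumor", self.tumor), ("recurrence", self.recurrence)):
            if lesion is None:
                continue
            if lesion.suvmax <= self.background_suv:
                raise ValueError(f"{name} SUVmax must exceed the background level")
            c = np.asarray(lesion.centroid_mm)
            a = np.asarray(lesion.semi_axes_mm)
            if np.any(c - a < np.asarray(dom.lower_mm) + margin) or np.any(
                c + a > np.asarray(dom.upper_mm) - margin
            ):
                raise ValueError(f"{name} lesion extends beyond the image grid")
        if self.recurrence is not None:
            body_c = np.asarray(self.anatomy.body_center_mm)
            body_a = np.asarray(self.anatomy.body_semi_axes_mm)
            rc = np.asarray(self.recurrence.centroid_mm)
            if float(np.sum(((rc - body_c) / body_a) ** 2)) > 0.85**2:
                raise ValueError("recurrence lesion centroid falls outside the body")


@dataclass
class PatientPhantom:
    """One simulated patient: paired scans, true transform, ground-truth masks."""

    config: PhantomConfig
    group: str
    baseline_pet: SuvImage
    baseline_anat: SuvImage
    followup_pet: SuvImage
    followup_anat: SuvImage
    true_transform: RigidTransform
    tumor_mask: BinaryMask              # lesion ellipsoid support, baseline grid
    recurrence_mask: BinaryMask | None  # baseline-space support of the planted lesion


# ---------------------------------------------------------------------------
# scene evaluation


def _ellipsoid_indicator(points: np.ndarray, center, semi_axes) -> np.ndarray:
    d = (points - np.asarray(center)) / np.asarray(semi_axes)
    return np.einsum("...i,...i->...", d, d) <= 1.0


def _kernel_field(points: np.ndarray, lesion: LesionSpec) -> np.ndarray:
    total = np.zeros(points.shape[:-1])
    axes = np.asarray(lesion.semi_axes_mm)
    centroid = np.asarray(lesion.centroid_mm)
    for k in lesion.kernels:
        center = centroid + np.asarray(k.center_frac) * axes
        sigma = k.sigma_frac * axes
        d = (points - center) / sigma
        r = np.sqrt(np.einsum("...i,...i->...", d, d))
        total += k.amplitude * np.exp(-(r**k.sharpness))
    return total


class _Scene:
    """Continuous baseline-coordinate scene for one phantom patient."""

    def __init__(self, config: PhantomConfig):
        self.cfg = config
        # normalization constants from the baseline grid sampling (in-support max)
        pts = config.grid.voxel_centers()
        self._kmax: dict[str, float] = {}
        for name, lesion in (("tumor", config.tumor), ("recurrence", config.recurrence)):
            if lesion is None:
                continue
            support = self._lesion_support(pts, lesion)
            if not support.any():
                raise ValueError(f"{name} lesion support contains no voxel centers")
            self._kmax[name] = float(_kernel_field(pts, lesion)[support].max())

    def _lesion_support(self, points: np.ndarray, lesion: LesionSpec) -> np.ndarray:
        anat = self.cfg.anatomy
        inside_body = _ellipsoid_indicator(points, anat.body_center_mm, anat.body_semi_axes_mm)
        return inside_body & _ellipsoid_indicator(points, lesion.centroid_mm, lesion.semi_axes_mm)

    def pet(self, points: np.ndarray, lesion_name: str | None) -> np.ndarray:
        cfg = self.cfg
        anat = cfg.anatomy
        inside = _ellipsoid_indicator(points, anat.body_center_mm, anat.body_semi_axes_mm)
        out = np.where(inside, cfg.background_suv, cfg.outside_suv).astype(float)
        lesion = getattr(cfg, lesion_name) if lesion_name else None
        if lesion is not None:
            support = self._lesion_support(points, lesion)
            k = _kernel_field(points, lesion) / self._kmax[lesion_name]
            out = out + support * (lesion.suvmax - cfg.background_suv) * k
        return out

    def anat(self, points: np.ndarray) -> np.ndarray:
        spec = self.cfg.anatomy
        inside = _ellipsoid_indicator(points, spec.body_center_mm, spec.body_semi_axes_mm)
        out = np.where(inside, spec.body_intensity, spec.outside_intensity).astype(float)
        for blob in spec.tissue_blobs:
            d = points - np.asarray(blob.center_mm)
            r2 = np.einsum("...i,...i->...", d, d)
            out = out + inside * blob.amplitude * np.exp(-0.5 * r2 / blob.sigma_mm**2)
        for s in spec.landmarks:
            d = points - np.asarray(s.center_mm)
            sphere = np.einsum("...i,...i->...", d, d) <= s.radius_mm**2
            out = np.where(sphere, s.intensity, out)
        return out


# ---------------------------------------------------------------------------
# lesion sizing

#: realized 40%-isocontour volume / single-kernel analytic volume for the
#: default multi-kernel uptake profiles (fixed calibration constant)
_V40_INFLATION = 1.26


def lesion_from_target_volume(
    centroid_mm,
    target_v40_cc: float,
    suvmax: float,
    background_suv: float = 1.5,
    axis_ratios=(1.0, 0.85, 0.75),
    kernels: tuple[UptakeKernel, ...] | None = None,
) -> LesionSpec:
    """Size a lesion so its dominant kernel's 40%-of-SUVmax isocontour
    encloses approximately ``target_v40_cc``.

    Solves the single-kernel model analytically: the 40% region of
    ``b + (S-b) exp(-r^p)`` is ``r <= (-ln u)^(1/p)`` with
    ``u = (0.4 S - b)/(S - b)``.  Satellite kernels enlarge the realized
    region by a near-constant factor (~1.26 for the default kernel sets,
    measured once on noise-free renders), which the sizing divides out.
    """
    if kernels is None:
        kernels = baseline_kernels()
    primary = max(kernels, key=lambda k: k.amplitude)
    u = (0.4 * suvmax - background_suv) / (suvmax - background_suv)
    if not (0.0 < u < 1.0):
        raise ValueError(f"SUVmax {suvmax} too low for a 40% threshold above background")
    rho = (-math.log(u)) ** (1.0 / primary.sharpness)
    target_mm3 = target_v40_cc * 1000.0 / _V40_INFLATION
    sigma_prod = target_mm3 * 3.0 / (4.0 * math.pi * rho**3)
    ratios = np.asarray(axis_ratios, dtype=float)
    a = (sigma_prod / (primary.sigma_frac**3 * float(np.prod(ratios)))) ** (1.0 / 3.0)
    return LesionSpec(
        centroid_mm=tuple(float(x) for x in centroid_mm),
        semi_axes_mm=tuple(a * ratios),
        suvmax=float(suvmax),
        kernels=tuple(kernels),
    )


def shifted_copy(lesion: LesionSpec, offset_mm) -> LesionSpec:
    """An exact translated replica of a lesion (same shape, kernels, SUVmax).

    With an integer-voxel offset, identity transform and zero noise, the
    replica's sampled uptake is the baseline lesion's array shifted by that
    many voxels — which makes the planted overlap computable in closed form
    by an independent array shift.
    """
    c = np.asarray(lesion.centroid_mm) + np.asarray(offset_mm, dtype=float)
    return replace(lesion, centroid_mm=tuple(c))


def default_patient_config(seed: int = 0, group: str = "LRRD") -> PhantomConfig:
    """A single representative phantom at the cohort's central parameters."""
    tumor = lesion_from_target_volume((10.0, 20.0, 0.0), 24.6, 14.3)
    recurrence = None
    if group == "LRRD":
        direction = np.array([0.8, 0.5, 0.33])
        direction /= np.linalg.norm(direction)
        offset = 0.55 * tumor.boundary_distance(direction)
        recurrence = lesion_from_target_volume(
            np.asarray(tumor.centroid_mm) + offset * direction,
            25.4, 14.3, kernels=recurrence_kernels(),
        )
    return PhantomConfig(tumor=tumor, recurrence=recurrence, seed=seed, group=group)


# ---------------------------------------------------------------------------
# generation


def generate_patient(config: PhantomConfig) -> PatientPhantom:
    """Render one phantom patient from its config (bit-deterministic in seed)."""
    config.validate()
    scene = _Scene(config)
    grid = config.grid
    pts = grid.voxel_centers()

    lesion_fu = "recurrence" if config.recurrence is not None else None
    base_pet = scene.pet(pts, "tumor")
    base_anat = scene.anat(pts)
    # the follow-up scan observes the scene through the repositioning transform:
    # image value at follow-up point x is the scene at M^-1(x)
    pts_fu = config.true_transform.inverse().apply(pts.reshape(-1, 3)).reshape(pts.shape)
    fu_pet = scene.pet(pts_fu, lesion_fu)
    fu_anat = scene.anat(pts_fu)

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        base_pet = base_pet + rng.normal(0.0, config.noise_sd, grid.shape)
        base_anat = base_anat + rng.normal(0.0, config.noise_sd, grid.shape)
        fu_pet = fu_pet + rng.normal(0.0, config.noise_sd, grid.shape)
        fu_anat = fu_anat + rng.normal(0.0, config.noise_sd, grid.shape)
    base_pet = np.maximum(base_pet, 0.0)
    fu_pet = np.maximum(fu_pet, 0.0)

    tumor_mask = BinaryMask(grid, scene._lesion_support(pts, config.tumor))
    rec_mask = None
    if config.recurrence is not None:
        rec_mask = BinaryMask(grid, scene._lesion_support(pts, config.recurrence))

    return PatientPhantom(
        config=config,
        group=config.resolved_group(),
        baseline_pet=SuvImage(grid, base_pet, "PET"),
        baseline_anat=SuvImage(grid, base_anat, "ANAT"),
        followup_pet=SuvImage(grid, fu_pet, "PET"),
        followup_anat=SuvImage(grid, fu_anat, "ANAT"),
        true_transform=config.true_transform,
        tumor_mask=tumor_mask,
        recurrence_mask=rec_mask,
    )


# ---------------------------------------------------------------------------
# cohort level


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level sampling distributions (the emulated clinical conditions)."""

    median_v40_cr_cc: float = 8.9
    v40_ratio_lrrd: float = 2.64         # median I40 ratio LRRD / CR
    v40_log_sd: float = 0.45             # lognormal log-SD of MTV(40%) targets
    suvmax_cr: tuple[float, float] = (13.2, 3.1)    # (mean, sd), truncated > suvmax_min
    suvmax_lrrd: tuple[float, float] = (16.1, 5.2)
    # fixed-percentage thresholding degenerates when 0.3 x SUVmax approaches the
    # background level (the component floods the body); the emulated clinical
    # cohort is uniformly high-uptake, so the floor sits well above that point
    suvmax_min: float = 7.0
    r40_log_sd: float = 0.30             # recurrence target = tumor target x exp(N(0, sd))
    edge_offset_frac: tuple[float, float] = (0.55, 0.95)  # of centroid-to-boundary distance
    # recurrence directions within the cone cos(angle) > this toward the dominant
    # baseline uptake focus are rejected: relapse sits at the rim of the uptake
    # distribution and spares the hottest sub-volume (set to 1.0 to disable)
    hotspot_avoidance_cos: float = 0.0
    # minimum clearance (mm) between the recurrence 40%-isocontour and the
    # dominant baseline focus: the hottest baseline sub-volume stays outside
    # the relapse volume, as observed clinically (set to 0 to disable)
    core_keepout_mm: float = 10.0
    centroid_mm: tuple[float, float, float] = (10.0, 20.0, 0.0)
    centroid_jitter_mm: float = 10.0
    axis_ratios: tuple[float, float, float] = (1.0, 0.85, 0.75)
    axis_jitter: float = 0.10
    translation_max_mm: float = 8.0
    rotation_max_deg: float = 4.0
    noise_sd: float = 0.1
    background_suv: float = 1.5


def sample_mtv40(group: str, n: int, rng: np.random.Generator,
                 params: CohortParams | None = None) -> np.ndarray:
    """Draw MTV(40%) targets (cc) from the cohort distribution of one group."""
    params = params or CohortParams()
    median = params.median_v40_cr_cc
    if group == "LRRD":
        median *= params.v40_ratio_lrrd
    elif group != "CR":
        raise ValueError(f"unknown group {group!r}")
    return median * np.exp(rng.normal(0.0, params.v40_log_sd, n))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return lo + sd  # pathological parameters only


def _patient_config(group: str, index: int, params: CohortParams, master_seed: int,
                    grid: VolumeGrid) -> PhantomConfig:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    rng = np.random.default_rng(ss)
    phantom_seed = int(np.random.SeedSequence(entropy=master_seed,
                                              spawn_key=(index, 1)).generate_state(1)[0])

    v40 = float(sample_mtv40(group, 1, rng, params)[0])
    suv_mean, suv_sd = params.suvmax_lrrd if group == "LRRD" else params.suvmax_cr
    suvmax = _truncated_normal(rng, suv_mean, suv_sd, params.suvmax_min)
    centroid = np.asarray(params.centroid_mm) + rng.uniform(
        -params.centroid_jitter_mm, params.centroid_jitter_mm, 3
    )
    ratios = np.asarray(params.axis_ratios) * rng.uniform(
        1 - params.axis_jitter, 1 + params.axis_jitter, 3
    )
    ratios = ratios / ratios.max()
    tumor = lesion_from_target_volume(centroid, v40, suvmax, params.background_suv, ratios)

    recurrence = None
    if group == "LRRD":
        primary = max(tumor.kernels, key=lambda k: k.amplitude)
        hotspot_off = np.asarray(primary.center_frac) * np.asarray(tumor.semi_axes_mm)
        hotspot_world = centroid + hotspot_off
        hotspot_dir = hotspot_off / np.linalg.norm(hotspot_off)
        rec_suvmax = _truncated_normal(rng, suv_mean, suv_sd, params.suvmax_min)
        rec_v40 = v40 * math.exp(rng.normal(0.0, params.r40_log_sd))
        for _ in range(300):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if float(direction @ hotspot_dir) > params.hotspot_avoidance_cos:
                continue
            frac = rng.uniform(*params.edge_offset_frac)
            rec_centroid = centroid + frac * tumor.boundary_distance(direction) * direction
            candidate = lesion_from_target_volume(
                rec_centroid, rec_v40, rec_suvmax, params.background_suv,
                ratios, kernels=recurrence_kernels(),
            )
            if params.core_keepout_mm > 0:
                to_hotspot = hotspot_world - rec_centroid
                dist = float(np.linalg.norm(to_hotspot))
                rp = max(candidate.kernels, key=lambda k: k.amplitude)
                u40 = (0.4 * rec_suvmax - params.background_suv) / (
                    rec_suvmax - params.background_suv
                )
                rho40 = (-math.log(u40)) ** (1.0 / rp.sharpness)
                iso_radius = rho40 * rp.sigma_frac * candidate.boundary_distance(to_hotspot)
                if dist < iso_radius + params.core_keepout_mm:
                    continue
            try:
                PhantomConfig(tumor=tumor, recurrence=candidate, grid=grid).validate()
            except ValueError:
                continue
            recurrence = candidate
            break
        if recurrence is None:
            raise ValueError(f"could not place recurrence lesion for patient {index}")

    transform = RigidTransform(
        translation_mm=tuple(rng.uniform(-params.translation_max_mm,
                                         params.translation_max_mm, 3)),
        rotation_deg=tuple(rng.uniform(-params.rotation_max_deg,
                                       params.rotation_max_deg, 3)),
        center_mm=tuple(grid.center_mm),
    )
    return PhantomConfig(
        tumor=tumor, recurrence=recurrence, grid=grid,
        background_suv=params.background_suv, noise_sd=params.noise_sd,
        true_transform=transform, seed=phantom_seed, group=group,
    )


def generate_cohort_configs(
    n_cr: int, n_lrrd: int, params: CohortParams | None = None, seed: int = 0,
    grid: VolumeGrid | None = None,
) -> list[PhantomConfig]:
    """Draw per-patient configs (CR first, then LRRD) from the cohort distributions.

    Each patient's randomness is derived from the master seed and the
    patient index alone, so patient k is identical regardless of cohort size.
    """
    if n_cr < 0 or n_lrrd < 0:
        raise ValueError("cohort counts must be >= 0")
    params = params or CohortParams()
    grid = grid or default_grid()
    configs = [_patient_config("CR", i, params, seed, grid) for i in range(n_cr)]
    configs += [_patient_config("LRRD", n_cr + i, params, seed, grid) for i in range(n_lrrd)]
    return configs


def generate_cohort(
    n_cr: int, n_lrrd: int, params: CohortParams | None = None, seed: int = 0,
    grid: VolumeGrid | None = None,
) -> list[PatientPhantom]:
    """Render a full cohort of phantom patients (reproducible under seed)."""
    return [generate_patient(c) for c in generate_cohort_configs(n_cr, n_lrrd, params, seed, grid)]
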