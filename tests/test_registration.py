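"""Rigid transforms, MI estimation, region derivation and resampling."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petsubvol.image_io import BinaryMask, SuvImage, VolumeGrid
from petsubvol.registration import (
    RegistrationOptions,
    RigidTransform,
    apply_rigid,
    derive_region,
    mutual_information,
    register_rigid,
)
from petsubvol.synthetic_phantom import default_patient_config, generate_patient


# --- RigidTransform ---------------------------------------------------------


def test_compose_with_inverse_is_identity(rng):
    for _ in range(20):
        tr = RigidTransform(
            tuple(rng.uniform(-20, 20, 3)),
            tuple(rng.uniform(-30, 30, 3)),
            tuple(rng.uniform(-50, 50, 3)),
        )
        pts = rng.uniform(-100, 100, (50, 3))
        back = tr.inverse().apply(tr.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)


_mm = st.floats(-40.0, 40.0, allow_nan=False)
_deg = st.floats(-90.0, 90.0, allow_nan=False)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    t=st.tuples(_mm, _mm, _mm),
    r=st.tuples(_deg, _deg, _deg),
    c=st.tuples(_mm, _mm, _mm),
)
def test_inverse_property_holds_for_arbitrary_transforms(t, r, c):
    tr = RigidTransform(t, r, c)
    pts = np.array([[0.0, 0.0, 0.0], [10.0, -20.0, 30.0], [-55.0, 5.0, 70.0]])
    np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-8)
    np.testing.assert_allclose(
        tr.inverse().rotation_matrix @ tr.rotation_matrix, np.eye(3), atol=1e-12
    )


def test_pure_translation_preserves_distances(rng):
    tr = RigidTransform((5.0, -3.0, 8.0), (0.0, 0.0, 0.0))
    pts = rng.uniform(-50, 50, (20, 3))
    moved = tr.apply(pts)
    d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
    np.testing.assert_allclose(d0, d1, atol=1e-9)
    np.testing.assert_allclose(moved - pts - np.array([5.0, -3.0, 8.0]), 0.0, atol=1e-12)


def test_transform_json_roundtrip(tmp_path):
    tr = RigidTransform((1.0, 2.0, 3.0), (4.0, 5.0, 6.0), (7.0, 8.0, 9.0))
    tr.save_json(tmp_path / "t.json")
    assert RigidTransform.load_json(tmp_path / "t.json") == tr


# --- derive_region ----------------------------------------------------------


def test_single_hot_voxel_region_is_margin_box():
    grid = VolumeGrid((32, 32, 32), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
    vals = np.zeros(grid.shape)
    vals[16, 16, 16] = 10.0
    img = SuvImage(grid, vals, "PET")
    box = derive_region(img, 0.30, 40.0)
    p = grid.index_to_world((16, 16, 16))
    np.testing.assert_allclose(box.lower_mm, p - 40)
    np.testing.assert_allclose(box.upper_mm, p + 40)


def test_fraction_zero_gives_whole_domain(rng, small_grid):
    from tests.conftest import random_suv_image

    img = random_suv_image(rng, small_grid)
    box = derive_region(img, 0.0, 0.0)
    assert box == img.grid.domain_box()


def test_region_contains_ground_truth_tumor(default_phantom):
    box = derive_region(default_phantom.baseline_pet)
    sel = np.argwhere(default_phantom.tumor_mask.membership)
    world = default_phantom.baseline_pet.grid.index_to_world(sel)
    assert np.all(world >= np.asarray(box.lower_mm) - 1e-9)
    assert np.all(world <= np.asarray(box.upper_mm) + 1e-9)


# --- mutual information -----------------------------------------------------


def test_mi_self_exceeds_permuted(rng, small_grid):
    from tests.conftest import random_suv_image

    img = random_suv_image(rng, small_grid)
    perm = SuvImage(small_grid, rng.permutation(img.values.ravel()).reshape(small_grid.shape))
    assert mutual_information(img, img) >= mutual_information(img, perm)


def test_mi_constant_image_is_zero(small_grid, rng):
    from tests.conftest import random_suv_image

    const = SuvImage(small_grid, np.full(small_grid.shape, 5.0))
    img = random_suv_image(rng, small_grid)
    assert mutual_information(const, img) == pytest.approx(0.0, abs=1e-12)


def test_mi_symmetric(rng, small_grid):
    from tests.conftest import random_suv_image

    a, b = random_suv_image(rng, small_grid), random_suv_image(rng, small_grid)
    assert mutual_information(a, b, bins=16) == pytest.approx(
        mutual_information(b, a, bins=16), abs=1e-9
    )


def test_mi_independent_noise_near_analytic_bias(rng):
    # independent images: MI estimate ~ chi2 bias (bins-1)^2 / (2N)
    grid = VolumeGrid((40, 40, 40), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
    bins = 16
    a = SuvImage(grid, rng.normal(10, 1, grid.shape).clip(0))
    b = SuvImage(grid, rng.normal(10, 1, grid.shape).clip(0))
    mi = mutual_information(a, b, bins=bins)
    bias = (bins - 1) ** 2 / (2 * grid.shape[0] ** 3)
    assert mi < 5 * bias


def test_mi_warns_on_tiny_region(rng):
    grid = VolumeGrid((4, 4, 4), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
    from tests.conftest import random_suv_image

    img = random_suv_image(rng, grid)
    with pytest.warns(UserWarning, match="unstable"):
        mutual_information(img, img, bins=32)


# --- apply_rigid ------------------------------------------------------------


def test_identity_resample_is_exact(rng, small_grid):
    from tests.conftest import random_suv_image

    img = random_suv_image(rng, small_grid)
    out = apply_rigid(img, RigidTransform(), small_grid, "TRILINEAR")
    np.testing.assert_allclose(out.values, img.values, atol=1e-6)


def test_integer_voxel_shift_nearest(rng, small_grid):
    from tests.conftest import random_suv_image

    img = random_suv_image(rng, small_grid)
    tr = RigidTransform((4.0, 0.0, 0.0), (0.0, 0.0, 0.0))  # one voxel in +x
    out = apply_rigid(img, tr, small_grid, "NEAREST")
    np.testing.assert_array_equal(out.values[:-1], img.values[1:])
    assert np.all(out.values[-1] == 0)


def test_trilinear_constant_stays_constant_interior(small_grid):
    img = SuvImage(small_grid, np.full(small_grid.shape, 7.0))
    tr = RigidTransform((1.7, -2.3, 0.9), (3.0, -2.0, 1.0), tuple(small_grid.center_mm))
    out = apply_rigid(img, tr, small_grid, "TRILINEAR")
    assert np.allclose(out.values[4:-4, 4:-4, 4:-4], 7.0, atol=1e-5)


def test_trilinear_bounded_by_input_range(rng, small_grid):
    from tests.conftest import random_suv_image

    img = random_suv_image(rng, small_grid)
    tr = RigidTransform((2.5, 1.5, -3.5), (5.0, -4.0, 2.0), tuple(small_grid.center_mm))
    out = apply_rigid(img, tr, small_grid, "TRILINEAR")
    assert out.values.max() <= img.values.max() + 1e-5
    assert out.values.min() >= min(0.0, float(img.values.min())) - 1e-5


def test_mask_resampling_preserves_binarity(rng, small_grid):
    m = BinaryMask(small_grid, rng.random(small_grid.shape) > 0.7)
    tr = RigidTransform((4.0, 4.0, 0.0), (0.0, 0.0, 0.0))
    out = apply_rigid(m, tr, small_grid)
    assert isinstance(out, BinaryMask)
    assert set(np.unique(out.membership)) <= {False, True}


# --- register_rigid ---------------------------------------------------------


def test_self_registration_returns_identity(default_phantom):
    region = derive_region(default_phantom.baseline_pet)
    res = register_rigid(default_phantom.baseline_anat, default_phantom.baseline_anat, region)
    assert res.converged
    assert np.abs(res.transform.translation_mm).max() < 0.1
    assert np.abs(res.transform.rotation_deg).max() < 0.1


def test_translation_only_recovery_within_half_voxel():
    cfg = default_patient_config(seed=17)
    true = RigidTransform((6.0, -4.0, 8.0), (0.0, 0.0, 0.0), tuple(cfg.grid.center_mm))
    ph = generate_patient(replace(cfg, true_transform=true, noise_sd=0.05))
    region = derive_region(ph.baseline_pet)
    res = register_rigid(
        ph.baseline_anat, ph.followup_anat, region,
        RegistrationOptions(optimize_rotation=False),
    )
    err = np.abs(np.asarray(res.transform.translation_mm) - true.translation_mm)
    assert err.max() < 2.0  # half of the 4 mm voxel
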