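"""Tests for the synthetic field generator: loop physics, masks, rotation
augmentation and void injection."""

import numpy as np
import pytest

from ptxshim.fieldsim import (
    CoilArraySpec,
    InvalidSpecError,
    PhantomSpec,
    RegionMask,
    VoidSpec,
    augment_rotations,
    build_mask,
    inject_nonuniformity,
    loop_field,
    quadrature_combined,
    rotate_slice,
    simulate_channel_fields,
    simulate_dataset,
    GeneratorConfig,
)
from ptxshim.shimcore import TargetMap, rmse_percent, ShimWeights
from ptxshim.fieldsim import ChannelFieldSlice


# ---------------------------------------------------------------------------
# loop physics
# ---------------------------------------------------------------------------

def test_on_axis_field_matches_closed_form():
    """On the loop axis the elliptic-integral field must reduce to the
    textbook on-axis expression a^2 / (2 (a^2 + z^2)^{3/2})."""
    a = 12.0
    z = np.linspace(-30, 30, 41)
    brho, bz = loop_field(np.zeros_like(z), z, a)
    expected = a**2 / (2.0 * (a**2 + z**2) ** 1.5)
    np.testing.assert_allclose(bz, expected, rtol=1e-6)
    np.testing.assert_allclose(brho, 0.0, atol=1e-12)


def test_opposed_coils_cancel_at_center():
    """Two identical coils at 0 and 180 degrees produce fields of equal
    magnitude and opposite phase at the exact center voxel."""
    coils = CoilArraySpec(n_channels=2, radius=30.0, loop_radius=8.0,
                          wavelength=30.0)
    phantom = PhantomSpec(grid_shape=(41, 41), semi_axes=(15.0, 15.0),
                          noise_level=0.0)
    vol = simulate_channel_fields(coils, phantom, n_slices=1, seed=0,
                                  normalize=False)
    center = vol.slices[0].values[:, 20, 20]
    combined = center[0] + center[1]
    assert abs(combined) == pytest.approx(0.0, abs=1e-12 * abs(center[0]))


def test_simulation_is_deterministic():
    coils = CoilArraySpec.for_grid((32, 32))
    phantom = PhantomSpec.for_grid((32, 32))
    v1 = simulate_channel_fields(coils, phantom, n_slices=2, seed=3)
    v2 = simulate_channel_fields(coils, phantom, n_slices=2, seed=3)
    for s1, s2 in zip(v1.slices, v2.slices):
        np.testing.assert_array_equal(s1.values, s2.values)
    for m1, m2 in zip(v1.masks, v2.masks):
        np.testing.assert_array_equal(m1.inside, m2.inside)


def test_invalid_specs_rejected():
    with pytest.raises(InvalidSpecError):
        CoilArraySpec(n_channels=0)
    with pytest.raises(InvalidSpecError):
        CoilArraySpec(loop_radius=-1.0)
    with pytest.raises(InvalidSpecError):
        PhantomSpec(semi_axes=(0.0, 10.0))
    with pytest.raises(InvalidSpecError):
        simulate_channel_fields(
            CoilArraySpec(radius=0.0), PhantomSpec(), n_slices=1, seed=0
        )


def test_quadrature_normalization(small_volume):
    """Stored slices are normalized: quadrature-mode in-mask mean |B1+| = 1."""
    coils = small_volume.metadata["coils"]
    for fields, mask in zip(small_volume.slices, small_volume.masks):
        cp = quadrature_combined(fields.values, coils.quadrature_phases)
        assert np.mean(np.abs(cp)[mask.inside]) == pytest.approx(1.0, rel=1e-12)


def test_quadrature_symmetry_under_coil_step_rotation():
    """For a circularly symmetric phantom and equally spaced identical coils
    the quadrature-combined magnitude is invariant under a 45-degree
    rotation (up to interpolation error)."""
    coils = CoilArraySpec.for_grid((61, 61))
    phantom = PhantomSpec(grid_shape=(61, 61), semi_axes=(22.0, 22.0),
                          noise_level=0.0)
    vol = simulate_channel_fields(coils, phantom, n_slices=1, seed=0)
    mag = np.abs(quadrature_combined(vol.slices[0].values,
                                     coils.quadrature_phases))
    from scipy.ndimage import rotate as ndrotate

    rotated = ndrotate(mag, 45.0, reshape=False, order=1, prefilter=False)
    inside = vol.masks[0].inside
    # compare away from the mask edge where interpolation bleeds
    from scipy.ndimage import binary_erosion

    core = binary_erosion(inside, iterations=3)
    assert np.median(np.abs(rotated[core] - mag[core])) < 0.02 * np.median(mag[core])


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_build_mask_threshold_and_flagging(caplog):
    assert build_mask(np.ones((4, 4)), 0.5).inside.all()
    with caplog.at_level("WARNING"):
        mask = build_mask(np.zeros((4, 4)), 0.5)
    assert mask.is_empty
    assert any("empty" in r.message for r in caplog.records)


def test_elliptical_mask_voxel_count():
    """Mask area equals the discrete ellipse voxel count computed directly
    from the ellipse inequality."""
    phantom = PhantomSpec(grid_shape=(41, 41), semi_axes=(14.0, 9.0),
                          noise_level=0.0)
    vol = simulate_channel_fields(
        CoilArraySpec.for_grid((41, 41)), phantom, n_slices=1, seed=0
    )
    yy, xx = np.mgrid[0:41, 0:41] - 20.0
    expected = int(np.sum((xx / 14.0) ** 2 + (yy / 9.0) ** 2 <= 1.0))
    assert vol.masks[0].n_voxels == expected


# ---------------------------------------------------------------------------
# rotation augmentation
# ---------------------------------------------------------------------------

def test_augment_identity_and_counts(small_volume):
    assert augment_rotations(small_volume, 1) is small_volume
    out = augment_rotations(small_volume, 4)
    assert out.n_slices == 4 * small_volume.n_slices
    angles = [s["rotation_deg"] for s in out.metadata["slices"]]
    assert angles[:4] == [0.0, 90.0, 180.0, 270.0]
    # zero-angle copies are bit-identical to the source
    np.testing.assert_array_equal(out.slices[0].values, small_volume.slices[0].values)


def test_paper_scale_slice_count_formula():
    """64 volumes x 32 slices x 12 rotations = 24,576 augmented slices; the
    desk-scale generator obeys the same product rule."""
    assert 64 * 32 * 12 == 24576
    cfg = GeneratorConfig(n_volumes=2, n_slices=3, n_rotations=4,
                          grid_shape=(32, 32))
    vols = simulate_dataset(cfg, seed=0)
    assert sum(v.n_slices for v in vols) == 2 * 3 * 4


def test_rotation_composition_roundtrip(small_volume):
    """Composing four 90-degree rotations returns the original slice within
    interpolation tolerance (exactly, for axis-aligned angles)."""
    f, m, d = small_volume.slices[0], small_volume.masks[0], small_volume.densities[0]
    for _ in range(4):
        f, m, d = rotate_slice(f, m, d, 90.0)
    np.testing.assert_allclose(f.values, small_volume.slices[0].values, atol=1e-10)
    np.testing.assert_array_equal(m.inside, small_volume.masks[0].inside)


def test_all_slices_have_nonempty_masks():
    vols = simulate_dataset(
        GeneratorConfig(n_volumes=2, n_slices=4, n_rotations=3, grid_shape=(32, 32)),
        seed=1,
    )
    for v in vols:
        assert all(not m.is_empty for m in v.masks)


# ---------------------------------------------------------------------------
# void injection
# ---------------------------------------------------------------------------

def test_void_injection_properties(small_slice):
    fields, mask, m = small_slice
    mag = np.abs(np.tensordot(np.ones(8) / 8, fields.values, axes=1))

    # depth 0: identity
    out = inject_nonuniformity(mag, mask, VoidSpec(radius=3.0, depth=0.0), seed=0)
    np.testing.assert_array_equal(out, mag)

    # depth 1 at a known center: that voxel goes to zero
    ci, cj = map(int, np.argwhere(mask.inside)[len(np.argwhere(mask.inside)) // 2])
    out = inject_nonuniformity(
        mag, mask, VoidSpec(radius=1.0, depth=1.0, center=(ci, cj)), seed=0
    )
    assert out[ci, cj] == pytest.approx(0.0, abs=1e-12)

    # masked RMSE vs a uniform target strictly increases after injection
    base = ChannelFieldSlice(mag[None].astype(complex))
    injected = ChannelFieldSlice(out[None].astype(complex))
    one = ShimWeights(np.array([1.0 + 0j]))
    assert rmse_percent(injected, one, m, mask) > rmse_percent(base, one, m, mask)

    with pytest.raises(InvalidSpecError):
        VoidSpec(radius=0.0, depth=0.5)
    with pytest.raises(ValueError, match="inside the mask"):
        inject_nonuniformity(mag, mask, VoidSpec(radius=2.0, depth=0.5, center=(0, 0)))
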