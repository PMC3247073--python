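"""Threshold masks, metric margin augmentation, sagittal mirroring."""

import numpy as np
import pytest

from endicom.dicom_io import CTVolume
from endicom.segmentation import (
    SegmentationMask,
    augment_margin,
    load_mask,
    mirror_mask,
    save_mask,
    threshold_segment,
)

from conftest import identity_geometry


def lattice_ball_count(margin_mm: float, spacing=(1.0, 1.0, 1.0)) -> int:
    """Brute-force: lattice points within Euclidean distance margin of the
    origin, with per-axis physical spacing (row, col, slice)."""
    s = np.array([spacing[2], spacing[0], spacing[1]])  # (k, i, j) axes
    r = np.ceil(margin_mm / s).astype(int)
    axes = [np.arange(-ri, ri + 1) * si for ri, si in zip(r, s)]
    kk, ii, jj = np.meshgrid(*axes, indexing="ij")
    return int((kk**2 + ii**2 + jj**2 <= margin_mm**2 + 1e-9).sum())


def single_voxel_mask(shape=(25, 25, 25), spacing=(1.0, 1.0, 1.0)):
    geom = identity_geometry(shape=shape, spacing=spacing)
    m = np.zeros(shape, bool)
    m[tuple(s // 2 for s in shape)] = True
    return SegmentationMask(m, geom, "seed")


def test_threshold_segment_trivial_bands(small_phantom):
    vol = small_phantom.volume
    full = threshold_segment(vol, vol.intensities.min(), vol.intensities.max())
    assert full.mask.all()
    empty = threshold_segment(vol, -5000.0, vol.intensities.min() - 1.0)
    assert not empty.mask.any()
    with pytest.raises(ValueError):
        threshold_segment(vol, 10.0, 0.0)


def test_threshold_recovers_analytic_sphere_count():
    """A 300 HU sphere in -50 HU background: thresholding [200, 400] finds
    exactly the brute-force rasterized sphere voxels."""
    geom = identity_geometry(shape=(24, 24, 24))
    coords = np.stack(np.meshgrid(*[np.arange(24)] * 3, indexing="ij"), -1)
    center, radius = np.array([12.0, 12.0, 12.0]), 6.0
    inside = np.sum((coords - center) ** 2, axis=-1) <= radius**2
    hu = np.where(inside, 300.0, -50.0)
    vol = CTVolume(hu, geom, bits_stored=12, pixel_representation=0)
    mask = threshold_segment(vol, 200.0, 400.0)
    assert mask.voxel_count == int(inside.sum())
    assert np.array_equal(mask.mask, inside)


def test_margin_zero_is_identity(small_phantom):
    tumor = small_phantom.masks["tumor_0"]
    out = augment_margin(tumor, 0.0)
    assert np.array_equal(out.mask, tumor.mask)


def test_margin_matches_lattice_enumeration_isotropic():
    """10 mm margin around a single voxel on a 1 mm grid: output voxel count
    equals the number of lattice points within Euclidean distance 10."""
    out = augment_margin(single_voxel_mask(), 10.0)
    assert out.voxel_count == lattice_ball_count(10.0)


def test_margin_matches_lattice_enumeration_anisotropic():
    spacing = (1.0, 1.0, 2.0)  # (row, col, slice) mm
    out = augment_margin(single_voxel_mask(shape=(21, 31, 31), spacing=spacing), 10.0)
    assert out.voxel_count == lattice_ball_count(10.0, spacing)
    # physical extent along the slice axis: >= 10 mm and < 12 mm beyond seed
    ks = np.nonzero(out.mask.any(axis=(1, 2)))[0]
    reach_mm = (ks.max() - 10) * 2.0  # seed slice is 10
    assert 10.0 <= reach_mm < 12.0


def test_box_metric_is_per_axis_superset():
    seed = single_voxel_mask()
    eu = augment_margin(seed, 6.0, metric="euclidean")
    box = augment_margin(seed, 6.0, metric="box")
    assert np.all(box.mask[eu.mask])
    assert box.voxel_count == 13**3  # per-axis +-6 voxels at 1 mm


def test_margin_monotone_and_composable():
    rng = np.random.default_rng(12)
    geom = identity_geometry(shape=(20, 20, 20))
    m = np.zeros((20, 20, 20), bool)
    m[tuple(rng.integers(4, 16, (6, 3)).T)] = True
    mask = SegmentationMask(m, geom)
    small = augment_margin(mask, 3.0)
    big = augment_margin(mask, 5.0)
    assert np.all(small.mask[mask.mask])      # input subset of output
    assert np.all(big.mask[small.mask])       # larger margin gives superset
    # triangle inequality: dilate(3) then dilate(2) subset of dilate(5)
    two_step = augment_margin(small, 2.0)
    assert np.all(big.mask[two_step.mask])


def test_margin_surface_clearance():
    """Minimum distance from input voxels to the augmented mask's complement
    is at least margin minus one voxel diagonal (brute force)."""
    seed = single_voxel_mask()
    out = augment_margin(seed, 10.0)
    inp = np.argwhere(seed.mask).astype(float)
    comp = np.argwhere(~out.mask).astype(float)
    clearance = np.linalg.norm(comp - inp, axis=1).min()
    assert clearance >= 10.0 - np.sqrt(3.0)
    assert clearance > 10.0  # metric dilation guarantee at voxel centers


def test_mirror_symmetric_mask_unchanged():
    geom = identity_geometry(shape=(8, 8, 9))  # 9 columns: center x = 4
    m = np.zeros((8, 8, 9), bool)
    m[3:5, 3:5, 3:6] = True  # symmetric about x = 4
    mask = SegmentationMask(m, geom)
    out = mirror_mask(mask, 4.0)
    assert np.array_equal(out.mask, m)


def test_double_mirror_is_identity_on_grid_aligned_plane():
    rng = np.random.default_rng(5)
    geom = identity_geometry(shape=(10, 12, 15))
    m = rng.random((10, 12, 15)) < 0.2
    m[:, :, :2] = False
    m[:, :, -2:] = False
    mask = SegmentationMask(m, geom)
    out = mirror_mask(mirror_mask(mask, 7.0), 7.0)
    assert np.array_equal(out.mask, m)


def test_mirror_reflects_sphere_centroid():
    geom = identity_geometry(shape=(24, 24, 32))
    coords = np.stack(np.meshgrid(np.arange(24), np.arange(24), np.arange(32),
                                  indexing="ij"), -1)
    center = np.array([12.0, 12.0, 9.0])  # (k, i, j): x = 9
    m = np.sum((coords - center) ** 2, axis=-1) <= 25.0
    out = mirror_mask(SegmentationMask(m, geom), plane_x_mm=15.5)
    c_in = np.argwhere(m).mean(axis=0)
    c_out = np.argwhere(out.mask).mean(axis=0)
    expected_j = 2 * 15.5 - c_in[2]
    assert abs(c_out[2] - expected_j) <= 1.0
    assert np.allclose(c_out[:2], c_in[:2], atol=1.0)
    assert abs(out.voxel_count - int(m.sum())) <= 0.05 * m.sum()


def test_mask_file_roundtrip(tmp_path, small_phantom):
    tumor = small_phantom.masks["tumor_0"]
    save_mask(tumor, tmp_path / "tumor")
    back = load_mask(tmp_path / "tumor", expected_geometry=tumor.geometry)
    assert np.array_equal(back.mask, tumor.mask)
    assert back.label == tumor.label
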