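"""Sentinel-voxel encoding/extraction: exactness, separability, quantization."""

import logging

import numpy as np
import pytest

from endicom.codec import EncodingPolicy, encode, extract, roundtrip_error
from endicom.dicom_io import CTVolume
from endicom.errors import CollisionError, FrameError, OutOfVolumeError, SeparabilityError
from endicom.geometry import patient_to_voxel, voxel_to_patient
from endicom.marking import AcquiredPoint, Frame, Histology, PointCloud

from conftest import identity_geometry


def flat_volume(shape=(12, 16, 16), hu=0.0, spacing=(1.0, 1.0, 1.0)):
    geom = identity_geometry(shape=shape, spacing=spacing)
    return CTVolume(np.full(shape, hu), geom, bits_stored=12,
                    pixel_representation=0)


def image_cloud(positions):
    return PointCloud(tuple(
        AcquiredPoint(f"p{n}", n + 1, np.asarray(p, float), Histology.MALIGNANT)
        for n, p in enumerate(positions)), Frame.IMAGE)


def test_empty_cloud_is_a_noop():
    vol = flat_volume()
    out = encode(vol, PointCloud((), Frame.IMAGE))
    assert np.array_equal(out.intensities, vol.intensities)


def test_single_point_at_voxel_center_changes_exactly_one_voxel():
    vol = flat_volume()
    out = encode(vol, image_cloud([(5.0, 6.0, 7.0)]))  # (x, y, z) -> voxel (7, 6, 5)
    diff = np.argwhere(out.intensities != vol.intensities)
    assert [tuple(v) for v in diff] == [(7, 6, 5)]
    assert out.intensities[7, 6, 5] == 3500.0
    assert out.bits_stored == 16  # widened so the sentinel is representable


def test_navigation_frame_cloud_rejected():
    vol = flat_volume()
    cloud = PointCloud(
        (AcquiredPoint("p", 1, np.zeros(3), Histology.MALIGNANT),),
        Frame.NAVIGATION)
    with pytest.raises(FrameError):
        encode(vol, cloud)


def test_native_voxel_above_ceiling_is_a_separability_error():
    vol = flat_volume()
    hu = vol.intensities.copy()
    hu[3, 3, 3] = 3400.0  # e.g. dense metal artifact
    with pytest.raises(SeparabilityError, match=r"\(3, 3, 3\)"):
        encode(vol.with_intensities(hu), image_cloud([(1.0, 1.0, 1.0)]))


def test_encode_is_idempotent_and_touches_only_targets():
    rng = np.random.default_rng(0)
    vol = flat_volume(hu=40.0)
    pts = rng.uniform(0, 11, (20, 3))
    cloud = image_cloud(pts)
    once = encode(vol, cloud)
    twice = encode(once, cloud)
    assert np.array_equal(once.intensities, twice.intensities)
    targets = {tuple(patient_to_voxel(vol.geometry, p)) for p in pts}
    diff = {tuple(v) for v in np.argwhere(once.intensities != vol.intensities)}
    assert diff == targets  # exactly min(|cloud|, distinct voxels) changed
    assert np.all(once.intensities[once.intensities != 40.0] == 3500.0)


def test_collision_policies(caplog):
    vol = flat_volume()
    cloud = image_cloud([(2.0, 2.0, 2.0), (2.1, 2.1, 2.1)])  # same nearest voxel
    with pytest.raises(CollisionError):
        encode(vol, cloud, EncodingPolicy(collision="error"))
    with caplog.at_level(logging.WARNING, logger="endicom.codec"):
        out = encode(vol, cloud, EncodingPolicy(collision="merge"))
    assert (out.intensities == 3500.0).sum() == 1
    assert any("shared by points [1, 2]" in r.getMessage() for r in caplog.records)


def test_out_of_volume_policies():
    vol = flat_volume()
    cloud = image_cloud([(2.0, 2.0, 2.0), (100.0, 0.0, 0.0)])
    with pytest.raises(OutOfVolumeError):
        encode(vol, cloud)
    out = encode(vol, cloud, EncodingPolicy(out_of_volume="skip"))
    assert (out.intensities == 3500.0).sum() == 1


def test_spherical_mark_radius_marks_neighborhood():
    vol = flat_volume()
    out = encode(vol, image_cloud([(5.0, 6.0, 7.0)]),
                 EncodingPolicy(mark_radius_mm=1.0))
    marked = np.argwhere(out.intensities == 3500.0)
    # 1 mm radius on a 1 mm grid: center + 6 face neighbors
    assert len(marked) == 7
    center = np.array([7, 6, 5])
    assert np.all(np.abs(marked - center).sum(axis=1) <= 1)


def test_extract_on_unmarked_volume_is_empty():
    report = extract(flat_volume())
    assert report.voxel_count == 0 and len(report.recovered) == 0


def test_extract_recovers_marked_voxel_centers():
    vol = flat_volume(hu=-1000.0)
    pts = [(1.2, 2.7, 3.4), (8.9, 0.3, 10.6), (4.0, 4.0, 4.0)]
    marked = encode(vol, image_cloud(pts))
    report = extract(marked, 3200.0)
    expected = {tuple(voxel_to_patient(vol.geometry,
                                       patient_to_voxel(vol.geometry, p)))
                for p in pts}
    got = {tuple(p.position) for p in report.recovered}
    assert got == expected
    assert report.voxel_count == len(expected)
    assert [p.sequence_number for p in report.recovered] == [1, 2, 3]
    assert report.recovered.frame is Frame.IMAGE


def test_threshold_separates_sentinel_from_native_ceiling():
    """Native max 3071 HU, 5 marks: threshold 3200 finds exactly 5 voxels."""
    vol = flat_volume()
    hu = vol.intensities.copy()
    hu[0, 0, 0] = 3071.0
    vol = vol.with_intensities(hu)
    pts = [(1.0, 1.0, 1.0), (3.0, 3.0, 3.0), (5.0, 5.0, 5.0),
           (7.0, 7.0, 7.0), (9.0, 9.0, 9.0)]
    report = extract(encode(vol, image_cloud(pts)), 3200.0)
    assert report.voxel_count == 5


def test_roundtrip_error_zero_at_voxel_centers():
    vol = flat_volume()
    pts = [(2.0, 3.0, 4.0), (5.0, 6.0, 7.0)]
    cloud = image_cloud(pts)
    report = extract(encode(vol, cloud))
    rt = roundtrip_error(cloud, report, vol.geometry)
    assert rt.max_mm == 0.0
    assert rt.unmatched_encoded == 0 and rt.unmatched_recovered == 0


@pytest.mark.parametrize("spacing,bound", [
    ((1.0, 1.0, 1.0), np.sqrt(3) / 2),
    ((0.5, 0.5, 0.5), np.sqrt(3) / 4),  # halving the voxel halves the bound
])
def test_quantization_bound_half_voxel_diagonal(spacing, bound):
    """Round-trip positional error never exceeds half the voxel diagonal,
    checked against 1000 random points."""
    vol = flat_volume(shape=(12, 16, 16), spacing=spacing)
    rng = np.random.default_rng(21)
    hi = (np.array([16, 16, 12]) - 1) * np.array([spacing[1], spacing[0], spacing[2]])
    pts = rng.uniform(0, 1, (1000, 3)) * hi
    cloud = image_cloud(pts)
    marked = encode(vol, cloud)
    report = extract(marked)
    rt = roundtrip_error(cloud, report, vol.geometry)
    assert rt.max_mm <= bound + 1e-12
    # brute-force check: each point's nearest recovered mark is within bound
    rec = report.recovered.positions()
    d = np.linalg.norm(pts[:, None, :] - rec[None, :, :], axis=-1).min(axis=1)
    assert d.max() <= bound + 1e-12


def test_policy_invariants():
    with pytest.raises(ValueError):
        EncodingPolicy(sentinel_hu=3000.0, max_native_hu=3100.0)
    with pytest.raises(ValueError):
        EncodingPolicy(collision="maybe")
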