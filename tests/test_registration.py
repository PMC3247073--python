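"""Closed-form rigid registration: recovery, residuals, degeneracy, gate."""

import math

import numpy as np
import pytest

from endicom.errors import DegenerateFiducialsError, InsufficientDataError
from endicom.registration import (
    FiducialSet,
    RigidTransform,
    apply_transform,
    compose,
    estimate_rigid,
    fre_monte_carlo,
    invert_transform,
    load_fiducials,
    random_rigid_transform,
    registration_gate,
    save_fiducials,
    tetrahedron_fiducials,
)

ROT90_Z = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def _fids(phys, img):
    phys = np.asarray(phys, float)
    return FiducialSet(tuple(f"F{i}" for i in range(len(phys))), phys,
                       np.asarray(img, float))


def tetra():
    return tetrahedron_fiducials(100.0)


def test_self_registration_is_identity():
    pts = tetra()
    t = estimate_rigid(_fids(pts, pts))
    assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(t.translation, 0, atol=1e-12)
    assert t.rms_error == pytest.approx(0.0, abs=1e-12)


def test_recovers_known_rotation_and_shift():
    pts = tetra()
    img = pts @ ROT90_Z.T + np.array([10.0, 0.0, 0.0])
    t = estimate_rigid(_fids(pts, img))
    assert np.max(np.abs(apply_transform(t, pts) - img)) < 1e-9
    assert t.rms_error < 1e-9
    assert np.allclose(t.rotation, ROT90_Z, atol=1e-9)


def test_noise_free_parameter_recovery_many_trials():
    """Noise-free synthetic pairs always recover the generating transform."""
    rms = fre_monte_carlo(1000, sigma_mm=0.0, seed=11)
    assert np.max(rms) < 1e-9


def test_mean_fre_under_quarter_mm_noise_within_gate():
    """With 0.25 mm per-axis noise on 4 fiducials spanning ~100 mm the mean
    RMS stays within the 0.8 mm registration acceptance gate."""
    rms = fre_monte_carlo(1000, sigma_mm=0.25, seed=13)
    assert rms.mean() <= 0.8


def test_rms_matches_brute_force_residuals():
    """FRE from the solver equals an independently computed residual RMS."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(3, 9))
        phys = rng.uniform(-80, 80, (n, 3))
        while np.linalg.svd(phys - phys.mean(0), compute_uv=False)[1] < 1e-6:
            phys = rng.uniform(-80, 80, (n, 3))
        img = phys @ random_rigid_transform(rng).rotation.T + rng.normal(0, 1, (n, 3))
        t = estimate_rigid(_fids(phys, img))
        acc = 0.0
        for p, q in zip(phys, img):
            r = [t.rotation[a] @ p + t.translation[a] - q[a] for a in range(3)]
            acc += r[0] ** 2 + r[1] ** 2 + r[2] ** 2
        assert t.rms_error == pytest.approx(math.sqrt(acc / n), abs=1e-12)


def test_estimate_equivariant_under_prerotation():
    rng = np.random.default_rng(3)
    phys = rng.uniform(-50, 50, (5, 3))
    img = phys @ ROT90_Z.T + np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.3, (5, 3))
    g = random_rigid_transform(rng)
    t = estimate_rigid(_fids(phys, img))
    t2 = estimate_rigid(_fids(apply_transform(g, phys), img))
    expected = compose(t, invert_transform(g))
    assert np.allclose(t2.rotation, expected.rotation, atol=1e-9)
    assert np.allclose(t2.translation, expected.translation, atol=1e-8)
    assert t2.rms_error == pytest.approx(t.rms_error, abs=1e-10)


def test_estimate_invariant_to_pair_order():
    rng = np.random.default_rng(9)
    phys = rng.uniform(-50, 50, (6, 3))
    img = phys @ ROT90_Z.T + 5.0 + rng.normal(0, 0.2, (6, 3))
    perm = rng.permutation(6)
    t1 = estimate_rigid(_fids(phys, img))
    t2 = estimate_rigid(_fids(phys[perm], img[perm]))
    assert np.allclose(t1.rotation, t2.rotation, atol=1e-12)
    assert np.allclose(t1.translation, t2.translation, atol=1e-12)
    assert t1.rms_error == pytest.approx(t2.rms_error, abs=1e-12)


def test_apply_invert_compose():
    t = RigidTransform(ROT90_Z, np.zeros(3))
    assert apply_transform(t, (1.0, 0.0, 0.0)) == pytest.approx((0.0, 1.0, 0.0))
    ident = RigidTransform.identity()
    p = np.array([3.0, -2.0, 7.0])
    assert apply_transform(ident, p) == pytest.approx(tuple(p))
    rng = np.random.default_rng(1)
    g = random_rigid_transform(rng)
    assert apply_transform(invert_transform(g), apply_transform(g, p)) == \
        pytest.approx(tuple(p), abs=1e-9)
    gg = invert_transform(invert_transform(g))
    assert np.allclose(gg.rotation, g.rotation, atol=1e-12)
    assert np.allclose(gg.translation, g.translation, atol=1e-12)
    c = compose(g, invert_transform(g))
    assert np.allclose(c.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(c.translation, 0, atol=1e-9)


@pytest.mark.parametrize("rms,threshold,expected", [
    (0.0, 0.8, True),
    (0.79, 0.8, True),
    (0.81, 0.8, False),
    (1.3, 0.8, False),  # a clinically observed deviation scale fails the gate
])
def test_registration_gate(rms, threshold, expected):
    t = RigidTransform(np.eye(3), np.zeros(3), rms)
    report = registration_gate(t, threshold)
    assert report.passed is expected
    assert report.rms_error == rms and report.threshold_mm == threshold


def test_degenerate_configurations_rejected():
    with pytest.raises(InsufficientDataError):
        _fids([[0, 0, 0], [1, 0, 0]], [[0, 0, 0], [1, 0, 0]])
    line = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]
    with pytest.raises(DegenerateFiducialsError):
        _fids(line, line)
    dup = [[0, 0, 0], [1, 0, 0], [1, 0, 1e-9], [0, 1, 0]]
    good = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
    with pytest.raises(DegenerateFiducialsError):
        _fids(good, dup)


def test_fiducial_table_roundtrip(tmp_path):
    pts = tetra()
    fids = _fids(pts, pts @ ROT90_Z.T + 3.0)
    path = tmp_path / "fiducials.csv"
    save_fiducials(fids, path)
    back = load_fiducials(path)
    assert back.labels == fids.labels
    assert np.array_equal(back.physical_points, fids.physical_points)
    assert np.array_equal(back.image_points, fids.image_points)


def test_fiducial_table_requires_header(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b\n1,2\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_fiducials(path)
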