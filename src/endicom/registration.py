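"""Paired-point rigid registration between the navigation and image frames.

The navigation workflow touches each fiducial marker (titanium miniscrew or
splint marker) with a tracked pointer, pairing its physical-frame position
with the position picked in the CT volume. The rigid transform aligning the
two point sets is found in closed form (orthogonal Procrustes on the
cross-covariance, with the usual sign correction so the solution is a proper
rotation, never a reflection). The root-mean-square residual over the
fitting fiducials — the fiducial registration error, FRE — is the quantity
clinical systems display at registration time; registration is accepted only
if it falls below a threshold (0.8 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tables import read_table
from .errors import DegenerateFiducialsError, InsufficientDataError

__all__ = [
    "FiducialSet",
    "RigidTransform",
    "GateReport",
    "estimate_rigid",
    "apply_transform",
    "invert_transform",
    "compose",
    "registration_gate",
    "load_fiducials",
    "save_fiducials",
    "random_rigid_transform",
    "fre_monte_carlo",
]

_DUPLICATE_TOL = 1e-6
_COLLINEAR_TOL = 1e-9

FIDUCIAL_COLUMNS = ["label", "phys_x", "phys_y", "phys_z", "img_x", "img_y", "img_z"]


def _collinear(points: np.ndarray) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= _COLLINEAR_TOL * max(s[0], 1.0)


@dataclass(frozen=True)
class FiducialSet:
    """Paired fiducial coordinates; pairing is by list position.

    ``physical_points`` are navigation-frame mm positions, ``image_points``
    the corresponding image-frame (LPS) positions.
    """

    labels: tuple[str, ...]
    physical_points: np.ndarray  # (n, 3) mm, navigation frame
    image_points: np.ndarray     # (n, 3) mm, image frame

    def __post_init__(self):
        phys = np.asarray(self.physical_points, dtype=float)
        img = np.asarray(self.image_points, dtype=float)
        labels = tuple(str(l) for l in self.labels)
        if phys.ndim != 2 or phys.shape[1] != 3 or img.shape != phys.shape:
            raise ValueError("physical_points and image_points must both be (n, 3)")
        if not (len(labels) == len(phys)):
            raise ValueError("one label per point pair required")
        if len(phys) < 3:
            raise InsufficientDataError(
                f"rigid registration needs at least 3 point pairs, got {len(phys)}")
        d = np.linalg.norm(img[:, None, :] - img[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) < _DUPLICATE_TOL:
            a, b = np.unravel_index(np.argmin(d), d.shape)
            raise DegenerateFiducialsError(
                f"image points {labels[a]!r} and {labels[b]!r} coincide "
                f"(separation {d[a, b]:.2e} mm)")
        if _collinear(phys) or _collinear(img):
            raise DegenerateFiducialsError(
                "fiducial configuration is collinear; a rigid transform is "
                "not uniquely determined")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "physical_points", phys)
        object.__setattr__(self, "image_points", img)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation`` with the RMS
    residual of the fit that produced it (0 for exactly constructed transforms)."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_error: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-9:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise ValueError("rotation matrix must be proper (det +1)")
        if self.rms_error < 0:
            raise ValueError("rms_error must be non-negative")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "rms_error", float(self.rms_error))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def estimate_rigid(fids: FiducialSet) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping physical points onto
    image points.

    Minimizes sum ||R p_i + t - q_i||^2 by centroid alignment plus orthogonal
    Procrustes: SVD of the centered cross-covariance, with the smallest
    singular direction's sign flipped when the unconstrained optimum is a
    reflection. ``rms_error`` is the fiducial registration error,
    sqrt(mean ||R p_i + t - q_i||^2).
    """
    p, q = fids.physical_points, fids.image_points
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # pragma: no cover - excluded by collinearity check
        raise DegenerateFiducialsError("rank-deficient fiducial configuration")
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    if np.linalg.det(r) < 0:  # pragma: no cover - sign correction guarantees +1
        raise DegenerateFiducialsError("no proper rotation fits this configuration")
    t = qc - r @ pc
    residuals = p @ r.T + t - q
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RigidTransform(r, t, rms)


def apply_transform(transform: RigidTransform, point) -> np.ndarray:
    """Apply ``R p + t`` to a 3-vector or an (N, 3) array of points."""
    p = np.asarray(point, dtype=float)
    return p @ transform.rotation.T + transform.translation


def invert_transform(transform: RigidTransform) -> RigidTransform:
    """Inverse transform ``(R^T, -R^T t)``; the RMS residual is carried over."""
    rt = transform.rotation.T
    return RigidTransform(rt, -rt @ transform.translation, transform.rms_error)


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``inner`` first, then ``outer``."""
    return RigidTransform(
        outer.rotation @ inner.rotation,
        outer.rotation @ inner.translation + outer.translation,
        max(outer.rms_error, inner.rms_error),
    )


@dataclass(frozen=True)
class GateReport:
    passed: bool
    rms_error: float
    threshold_mm: float

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (f"registration {verdict}: RMS {self.rms_error:.3f} mm "
                f"(gate {self.threshold_mm:.3f} mm)")


def registration_gate(transform: RigidTransform, threshold_mm: float = 0.8) -> GateReport:
    """Accept a registration iff its RMS residual is within the gate.

    Clinical practice repeats the registration when the displayed RMS is
    unacceptable; 0.8 mm is the upper end of the usual acceptance band.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    return GateReport(transform.rms_error <= threshold_mm,
                      transform.rms_error, float(threshold_mm))


def load_fiducials(path) -> FiducialSet:
    """Read fiducial pairs from a delimited text table.

    Header required, columns ``label, phys_x, phys_y, phys_z, img_x, img_y,
    img_z``; mm units; comma, tab or whitespace delimited.
    """
    df = read_table(path)
    missing = [c for c in FIDUCIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fiducial table {path} missing columns: {missing}")
    return FiducialSet(
        labels=tuple(df["label"].astype(str)),
        physical_points=df[["phys_x", "phys_y", "phys_z"]].to_numpy(float),
        image_points=df[["img_x", "img_y", "img_z"]].to_numpy(float),
    )


def save_fiducials(fids: FiducialSet, path) -> None:
    df = pd.DataFrame({
        "label": fids.labels,
        "phys_x": fids.physical_points[:, 0],
        "phys_y": fids.physical_points[:, 1],
        "phys_z": fids.physical_points[:, 2],
        "img_x": fids.image_points[:, 0],
        "img_y": fids.image_points[:, 1],
        "img_z": fids.image_points[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def random_rigid_transform(rng: np.random.Generator,
                           max_translation_mm: float = 50.0) -> RigidTransform:
    """Uniformly random proper rotation (QR of a Gaussian matrix with sign
    fix) plus a uniform translation; used by simulations and property tests."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(q, t)


def tetrahedron_fiducials(edge_mm: float = 100.0) -> np.ndarray:
    """Vertices of a regular tetrahedron with the given edge length (mm),
    centered at the origin — the canonical 4-marker test configuration."""
    v = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                  [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    return v * (edge_mm / (2.0 * np.sqrt(2.0)))


def fre_monte_carlo(n_trials: int, sigma_mm: float, seed: int,
                    fiducials: np.ndarray | None = None) -> np.ndarray:
    """RMS fiducial registration errors over Monte-Carlo replicates.

    Each replicate moves the marker configuration (default: a regular
    tetrahedron of 100 mm edge) by a random rigid transform, perturbs the
    image-side points with isotropic Gaussian noise of per-axis standard
    deviation ``sigma_mm``, and re-estimates the transform. Returns the
    ``n_trials`` RMS residuals.
    """
    if fiducials is None:
        fiducials = tetrahedron_fiducials(100.0)
    rng = np.random.default_rng(seed)
    labels = tuple(f"F{i + 1}" for i in range(len(fiducials)))
    out = np.empty(n_trials)
    for trial in range(n_trials):
        t = random_rigid_transform(rng)
        image = apply_transform(t, fiducials)
        image = image + rng.normal(0.0, sigma_mm, size=image.shape)
        est = estimate_rigid(FiducialSet(labels, fiducials, image))
        out[trial] = est.rms_error
    return out
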