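"""Voxel <-> patient coordinate mapping of a CT series.

Conventions, fixed once for the whole package:

* The patient frame is DICOM LPS (x toward patient Left, y Posterior,
  z Superior), all coordinates in millimetres.
* Voxel indices are 0-based triples ``(k, i, j)`` = (slice, row, column).
* :attr:`VolumeGeometry.origin` is the patient-frame position of the
  **center** of voxel ``(0, 0, 0)`` — DICOM ImagePositionPatient semantics.
* Nearest-voxel rounding is round-half-even per axis, so ties are
  deterministic and reproducible across runs.

The forward map is the standard DICOM affine

    p = origin + i * spacing_row * row_direction
               + j * spacing_col * column_direction
               + k * spacing_slice * slice_direction

where ``row_direction`` is the patient-frame axis along which the row index
increases (the second ImageOrientationPatient triplet) and
``column_direction`` the axis of increasing column index (the first triplet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, OutOfVolumeError

__all__ = [
    "VolumeGeometry",
    "voxel_to_patient",
    "patient_to_voxel",
    "voxel_grid_patient_coords",
]

_UNIT_TOL = 1e-9
_ORTHO_TOL = 1e-6


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > _UNIT_TOL:
        raise GeometryError(f"{name} must be unit length (|v| = {n!r})")
    return v


@dataclass(frozen=True)
class VolumeGeometry:
    """Affine mapping between voxel indices and patient-frame mm coordinates.

    Parameters
    ----------
    origin
        Patient-frame position (mm) of the center of voxel (0, 0, 0).
    row_direction, column_direction, slice_direction
        Unit patient-frame axes of increasing row, column and slice index.
    spacing
        (row, column, slice) spacing in mm/voxel; all strictly positive.
    shape
        (slices, rows, columns); all components >= 1.
    """

    origin: np.ndarray
    row_direction: np.ndarray
    column_direction: np.ndarray
    slice_direction: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]
    _index_to_mm: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        if origin.shape != (3,) or not np.all(np.isfinite(origin)):
            raise GeometryError("origin must be a finite 3-vector")
        rd = _as_unit(self.row_direction, "row_direction")
        cd = _as_unit(self.column_direction, "column_direction")
        sd = _as_unit(self.slice_direction, "slice_direction")
        for a, b, na, nb in ((rd, cd, "row", "column"), (rd, sd, "row", "slice"),
                             (cd, sd, "column", "slice")):
            if abs(float(np.dot(a, b))) > _ORTHO_TOL:
                raise GeometryError(f"{na}_direction and {nb}_direction are not orthogonal")
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
            raise GeometryError(f"spacing must be three strictly positive values, got {spacing}")
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GeometryError(f"shape must be three integers >= 1, got {self.shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "row_direction", rd)
        object.__setattr__(self, "column_direction", cd)
        object.__setattr__(self, "slice_direction", sd)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)
        # Columns map (k, i, j) index steps to mm displacements.
        m = np.column_stack([sd * spacing[2], rd * spacing[0], cd * spacing[1]])
        object.__setattr__(self, "_index_to_mm", m)

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of the voxel body diagonal in mm."""
        return float(np.linalg.norm(self.spacing))

    @property
    def direction_matrix(self) -> np.ndarray:
        """Orthonormal 3x3 matrix with columns (slice, row, column) directions."""
        return np.column_stack(
            [self.slice_direction, self.row_direction, self.column_direction]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "VolumeGeometry":
        """Geometry of the same lattice after rigidly moving the patient frame
        by ``p -> rotation @ p + translation``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return VolumeGeometry(
            origin=rotation @ self.origin + translation,
            row_direction=rotation @ self.row_direction,
            column_direction=rotation @ self.column_direction,
            slice_direction=rotation @ self.slice_direction,
            spacing=self.spacing,
            shape=self.shape,
        )


def _check_index(geom: VolumeGeometry, idx) -> np.ndarray:
    idx = np.asarray(idx)
    scalar = idx.ndim == 1
    idx = np.atleast_2d(idx)
    if idx.shape[-1] != 3:
        raise ValueError("voxel index must be a (k, i, j) triple")
    shape = np.asarray(geom.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        bad = idx[np.any((idx < 0) | (idx >= shape), axis=1)][0]
        raise IndexError(f"voxel index {tuple(bad)} outside volume shape {geom.shape}")
    return idx[0] if scalar else idx


def voxel_to_patient(geom: VolumeGeometry, idx) -> np.ndarray:
    """Patient-frame mm position of the center of voxel ``idx = (k, i, j)``.

    ``idx`` may be a single triple or an (N, 3) array of triples; the result
    has the matching shape. Raises ``IndexError`` for out-of-range indices.
    """
    idx = _check_index(geom, idx)
    return geom.origin + np.asarray(idx, dtype=float) @ geom._index_to_mm.T


def patient_to_voxel(geom: VolumeGeometry, point, mode: str = "nearest"):
    """Invert :func:`voxel_to_patient`.

    Parameters
    ----------
    point
        Patient-frame mm position, a 3-vector or (N, 3) array.
    mode
        ``"continuous"`` returns fractional (k, i, j) coordinates;
        ``"nearest"`` rounds each axis half-to-even and returns integer
        indices, raising :class:`OutOfVolumeError` for points farther than
        half a voxel beyond the outermost voxel centers.
    """
    if mode not in ("nearest", "continuous"):
        raise ValueError(f"mode must be 'nearest' or 'continuous', got {mode!r}")
    p = np.asarray(point, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[-1] != 3:
        raise ValueError("point must be a 3-vector or (N, 3) array")
    # directions orthonormal -> inverse of index_to_mm is diag(1/s) @ D^T
    d = geom._index_to_mm / np.sum(geom._index_to_mm**2, axis=0)  # columns / s^2
    cont = (p - geom.origin) @ d
    if mode == "continuous":
        return cont[0] if scalar else cont
    rounded = np.rint(cont)  # round-half-even per axis
    shape = np.asarray(geom.shape)
    out = (cont < -0.5) | (cont > shape - 0.5)
    if np.any(out):
        bad = p[np.any(out, axis=1)][0]
        raise OutOfVolumeError(
            f"point {tuple(bad)} mm lies outside the volume lattice "
            f"(shape {geom.shape})", point=bad)
    idx = np.clip(rounded, 0, shape - 1).astype(np.int64)
    return idx[0] if scalar else idx


def voxel_grid_patient_coords(geom: VolumeGeometry) -> np.ndarray:
    """Patient coordinates of every voxel center, shape ``geom.shape + (3,)``.

    Convenience for whole-volume operations (mirroring, resampling).
    """
    ks, is_, js = np.meshgrid(
        np.arange(geom.shape[0]), np.arange(geom.shape[1]), np.arange(geom.shape[2]),
        indexing="ij",
    )
    idx = np.stack([ks, is_, js], axis=-1).astype(float)
    return geom.origin + idx @ geom._index_to_mm.T
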