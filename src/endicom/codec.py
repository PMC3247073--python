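"""Sentinel-voxel encoding and threshold recovery of landmark points.

The idea: a CT volume whose native intensities stay within the conventional
range (at most ~3100 HU, and exactly 3071 HU for 12-bit encodings) has
head-room above it. Writing each selected landmark into its nearest voxel
at a sentinel value of 3500 HU leaves the marks unambiguously separable —
any threshold strictly between the native ceiling and the sentinel (3200 HU
by default, for maximal margin on both sides) recovers exactly the marked
voxels, in any downstream platform that can threshold. The marks also make
the manipulation of the data set obvious to a reader.

What the voxel payload cannot carry — specimen names, sequence numbers,
histology — travels in a sidecar point table written next to the series.

Encoding is intentionally strict: if any native voxel already exceeds the
declared native ceiling (dense metal artifact, for instance), encoding
fails with a separability error rather than silently producing marks that
thresholding could confuse with anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dicom_io import CTVolume, widen_for_hu
from .errors import CollisionError, FrameError, OutOfVolumeError, SeparabilityError
from .geometry import VolumeGeometry, patient_to_voxel, voxel_to_patient
from .marking import AcquiredPoint, Frame, PointCloud

__all__ = [
    "EncodingPolicy",
    "ExtractionReport",
    "RoundTripReport",
    "encode",
    "extract",
    "roundtrip_error",
]

logger = logging.getLogger(__name__)

RECOVERED_POINT_NAME = "recovered"


@dataclass(frozen=True)
class EncodingPolicy:
    """How landmark points are written into the volume.

    sentinel_hu
        Value given to marked voxels; 3500 HU by default, far above any
        native CT intensity.
    max_native_hu
        Documented ceiling of unmodified data (default 3100 HU); encoding
        verifies the volume respects it.
    collision
        ``"merge"`` lets several points share one voxel (logged with their
        sequence numbers); ``"error"`` refuses.
    out_of_volume
        ``"error"`` refuses points outside the lattice; ``"skip"`` drops
        them with a warning.
    mark_radius_mm
        0 marks the single nearest voxel per point; a positive radius marks
        every voxel whose center lies within that distance of the point —
        purely a visibility aid for viewers that render single voxels poorly.
    """

    sentinel_hu: float = 3500.0
    max_native_hu: float = 3100.0
    collision: str = "merge"
    out_of_volume: str = "error"
    mark_radius_mm: float = 0.0

    def __post_init__(self):
        if self.sentinel_hu <= self.max_native_hu:
            raise ValueError(
                f"sentinel_hu ({self.sentinel_hu}) must exceed max_native_hu "
                f"({self.max_native_hu}); otherwise marks are not separable")
        if self.collision not in ("merge", "error"):
            raise ValueError("collision must be 'merge' or 'error'")
        if self.out_of_volume not in ("error", "skip"):
            raise ValueError("out_of_volume must be 'error' or 'skip'")
        if self.mark_radius_mm < 0:
            raise ValueError("mark_radius_mm must be >= 0")


@dataclass(frozen=True)
class ExtractionReport:
    """Result of threshold recovery: one point per super-threshold voxel,
    positioned at that voxel's center."""

    recovered: PointCloud
    voxel_count: int
    threshold_used: float


@dataclass(frozen=True)
class RoundTripReport:
    """Greedy nearest-pair match between encoded and recovered points."""

    distances_mm: np.ndarray
    unmatched_encoded: int = 0
    unmatched_recovered: int = 0

    @property
    def max_mm(self) -> float:
        return float(np.max(self.distances_mm)) if len(self.distances_mm) else 0.0

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.distances_mm)) if len(self.distances_mm) else 0.0


def _target_voxels(geom: VolumeGeometry, cloud: PointCloud, policy: EncodingPolicy):
    """Map each point to its voxel set; yields (point, [(k,i,j), ...])."""
    for point in cloud:
        try:
            center = patient_to_voxel(geom, point.position, mode="nearest")
        except OutOfVolumeError:
            if policy.out_of_volume == "error":
                raise
            logger.warning("point %d (%s) at %s mm is outside the volume; skipped",
                           point.sequence_number, point.name, point.position)
            continue
        voxels = [tuple(int(v) for v in center)]
        if policy.mark_radius_mm > 0:
            r = policy.mark_radius_mm
            span = np.ceil(r / geom.spacing).astype(int)  # (row, col, slice)
            k0, i0, j0 = voxels[0]
            kk = np.arange(max(0, k0 - span[2]), min(geom.shape[0], k0 + span[2] + 1))
            ii = np.arange(max(0, i0 - span[0]), min(geom.shape[1], i0 + span[0] + 1))
            jj = np.arange(max(0, j0 - span[1]), min(geom.shape[2], j0 + span[1] + 1))
            grid = np.stack(np.meshgrid(kk, ii, jj, indexing="ij"), axis=-1).reshape(-1, 3)
            centers = voxel_to_patient(geom, grid)
            near = np.linalg.norm(centers - point.position, axis=1) <= r + 1e-12
            voxels = sorted({tuple(int(v) for v in g) for g in grid[near]} | set(voxels))
        yield point, voxels


def encode(vol: CTVolume, cloud: PointCloud,
           policy: EncodingPolicy = EncodingPolicy()) -> CTVolume:
    """Write each point of an image-frame cloud into a copy of the volume as
    a sentinel-intensity voxel.

    The nearest voxel to each point is set to ``policy.sentinel_hu``; every
    other voxel is bit-identical to the input. The stored-pixel encoding is
    widened (signed 16-bit) when the sentinel exceeds the volume's declared
    ceiling. Fails with :class:`SeparabilityError` if any native voxel
    already exceeds ``policy.max_native_hu``.
    """
    if cloud.frame is not Frame.IMAGE:
        raise FrameError(
            "cloud must be in the image frame; apply to_image_frame first")
    # Voxels at exactly the sentinel value are existing marks, not native
    # anatomy — re-encoding an already marked volume is a no-op (idempotence).
    native = np.where(vol.intensities == policy.sentinel_hu, -np.inf, vol.intensities)
    if native.size and float(native.max()) > policy.max_native_hu:
        k, i, j = np.unravel_index(int(np.argmax(native)), native.shape)
        raise SeparabilityError(
            f"native voxel ({k}, {i}, {j}) has {vol.intensities[k, i, j]} HU, above "
            f"the declared native ceiling {policy.max_native_hu} HU; sentinel "
            f"marks would not be separable by thresholding")

    owners: dict[tuple[int, int, int], list[int]] = {}
    for point, voxels in _target_voxels(vol.geometry, cloud, policy):
        for v in voxels:
            owners.setdefault(v, []).append(point.sequence_number)

    collisions = {v: seqs for v, seqs in owners.items() if len(seqs) > 1}
    if collisions:
        if policy.collision == "error":
            v, seqs = next(iter(collisions.items()))
            raise CollisionError(
                f"points {seqs} map to the same voxel {v}; use the merge "
                f"policy to allow shared voxels")
        for v, seqs in sorted(collisions.items()):
            logger.warning("voxel %s shared by points %s (merged)", v, seqs)

    out = widen_for_hu(vol, policy.sentinel_hu)
    intensities = out.intensities.copy()
    for (k, i, j) in owners:
        intensities[k, i, j] = policy.sentinel_hu
    return out.with_intensities(intensities)


def extract(vol: CTVolume, threshold_hu: float = 3200.0) -> ExtractionReport:
    """Recover marked voxels by thresholding.

    Every voxel with intensity >= ``threshold_hu`` becomes one recovered
    point at the voxel's center, numbered in lexicographic (slice, row,
    column) order. An empty recovery is a valid result.
    """
    mask = vol.intensities >= threshold_hu
    idx = np.argwhere(mask)  # lexicographic (k, i, j) order
    points = tuple(
        AcquiredPoint(
            name=RECOVERED_POINT_NAME,
            sequence_number=n + 1,
            position=voxel_to_patient(vol.geometry, v),
        )
        for n, v in enumerate(idx)
    )
    return ExtractionReport(
        recovered=PointCloud(points, Frame.IMAGE),
        voxel_count=int(mask.sum()),
        threshold_used=float(threshold_hu),
    )


def roundtrip_error(cloud: PointCloud, report: ExtractionReport,
                    geom: VolumeGeometry) -> RoundTripReport:
    """Distances between encoded points and their recovered counterparts.

    Pairs are matched greedily by increasing distance (each point used at
    most once). For single-voxel marks without collisions every distance is
    bounded by half the voxel diagonal — the quantization cost of rounding a
    point to its nearest voxel center. A cardinality mismatch (after
    collision merging, or with finite mark radius) is reported, not fatal.
    """
    if len(cloud) < 1:
        raise ValueError("need at least one encoded point")
    a = cloud.positions()
    b = report.recovered.positions()
    if len(b) == 0:
        return RoundTripReport(np.empty(0), unmatched_encoded=len(a),
                               unmatched_recovered=0)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    free_a = np.ones(len(a), dtype=bool)
    free_b = np.ones(len(b), dtype=bool)
    dists = []
    for _ in range(min(len(a), len(b))):
        masked = np.where(np.outer(free_a, free_b), d, np.inf)
        ia, ib = np.unravel_index(np.argmin(masked), masked.shape)
        dists.append(masked[ia, ib])
        free_a[ia] = False
        free_b[ib] = False
    return RoundTripReport(
        distances_mm=np.asarray(dists),
        unmatched_encoded=int(free_a.sum()),
        unmatched_recovered=int(free_b.sum()),
    )
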