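"""Synthetic head CT phantoms with fiducial markers and ground truth.

Every capability of the package is testable without clinical data against
these phantoms: an ellipsoidal head (soft tissue inside a bone shell in
air), spherical tumor inclusions, and four bright fiducial blobs at exactly
known positions standing in for titanium miniscrews / splint markers. All
native intensities stay at or below 3071 HU — the 12-bit CT ceiling — which
is the premise that makes a 3500 HU sentinel separable. The fiducial blobs
are rendered at 3000 HU: metal-bright, but under the ceiling.

Generation is a pure function of the spec (identical bytes for identical
specs). :func:`simulate_navigation` then emulates the intraoperative side:
a random rigid transform defines the navigation frame, fiducial touch-offs
are perturbed with isotropic Gaussian localization noise, and specimen
points are acquired at known ground-truth positions inside the head with a
reproducible histology assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dicom_io import CTVolume
from .errors import PhantomSpecError
from .geometry import VolumeGeometry, voxel_grid_patient_coords
from .marking import AcquiredPoint, Frame, Histology, PointCloud
from .registration import (
    FiducialSet,
    RigidTransform,
    apply_transform,
    invert_transform,
    random_rigid_transform,
)
from .segmentation import SegmentationMask

__all__ = ["PhantomSpec", "Phantom", "NavigationSimulation",
           "make_phantom", "simulate_navigation"]

# default fiducial layout: 4 screw-like markers on/near the skull, spanning
# ~100 mm, non-coplanar (mm, LPS, head centered at the origin)
DEFAULT_FIDUCIALS = (
    (48.0, 0.0, -5.0),
    (-48.0, 0.0, -5.0),
    (0.0, 55.0, 0.0),
    (0.0, -40.0, 18.0),
)

DEFAULT_TUMORS = (((18.0, 24.0, -10.0), 8.0, 300.0),)  # (center mm, radius mm, HU)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines a phantom, hence its bytes.

    Defaults give a 64x128x128 volume at 1 mm isotropic spacing — large
    enough for a head-like cross-section, small enough for seconds-scale
    tests — with one 8 mm tumor sphere and four fiducial markers.
    """

    shape: tuple[int, int, int] = (64, 128, 128)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (row, col, slice) mm
    background_hu: float = -1000.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 1200.0
    fiducial_hu: float = 3000.0
    native_max_hu: float = 3071.0
    head_axes_mm: tuple[float, float, float] = (50.0, 58.0, 26.0)  # (x, y, z) semi-axes
    shell_thickness_mm: float = 4.0
    tumors: tuple = DEFAULT_TUMORS
    fiducials: tuple = DEFAULT_FIDUCIALS
    fiducial_radius_mm: float = 2.0
    noise_sigma_hu: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for hu in (self.background_hu, self.soft_tissue_hu, self.bone_hu,
                   self.fiducial_hu):
            if hu > self.native_max_hu:
                raise PhantomSpecError(
                    f"material intensity {hu} HU exceeds native ceiling "
                    f"{self.native_max_hu} HU")
        pts = np.asarray(self.fiducials, dtype=float)
        if len(pts) < 3:
            raise PhantomSpecError("at least 3 fiducials required")
        c = pts - pts.mean(axis=0)
        if np.linalg.svd(c, compute_uv=False)[1] < 1e-9:
            raise PhantomSpecError("fiducials are collinear")

    def geometry(self) -> VolumeGeometry:
        """Axis-aligned LPS geometry with the volume centered on the origin."""
        shape = np.asarray(self.shape)
        sp = np.asarray(self.spacing, dtype=float)
        extent = (shape - 1) * np.array([sp[2], sp[0], sp[1]])  # (z, y, x) span
        origin = np.array([-extent[2] / 2, -extent[1] / 2, -extent[0] / 2])
        return VolumeGeometry(
            origin=origin,
            row_direction=np.array([0.0, 1.0, 0.0]),
            column_direction=np.array([1.0, 0.0, 0.0]),
            slice_direction=np.array([0.0, 0.0, 1.0]),
            spacing=sp,
            shape=tuple(int(s) for s in shape),
        )


@dataclass(frozen=True)
class Phantom:
    volume: CTVolume
    fiducials: FiducialSet  # physical == image == exact marker centers
    masks: dict = field(default_factory=dict)  # label -> SegmentationMask


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Rasterize the phantom; deterministic given ``spec`` (including seed).

    Returns the CT volume (12-bit unsigned encoding, slope 1, intercept
    -1024), the exact fiducial coordinates, and analytic ground-truth masks
    for the head, bone shell and each tumor sphere.
    """
    geom = spec.geometry()
    coords = voxel_grid_patient_coords(geom)  # shape + (3,)
    ax = np.asarray(spec.head_axes_mm, dtype=float)
    half_extent = np.array([
        (geom.shape[2] - 1) * spec.spacing[1] / 2,  # x (columns)
        (geom.shape[1] - 1) * spec.spacing[0] / 2,  # y (rows)
        (geom.shape[0] - 1) * spec.spacing[2] / 2,  # z (slices)
    ])
    if np.any(ax >= half_extent):
        raise PhantomSpecError(
            f"head semi-axes {tuple(ax)} mm do not fit inside the half-extent "
            f"{tuple(half_extent)} mm of the requested grid")

    r_outer = np.sum((coords / ax) ** 2, axis=-1)
    inner_ax = ax - spec.shell_thickness_mm
    if np.any(inner_ax <= 0):
        raise PhantomSpecError("shell thicker than the head semi-axes")
    r_inner = np.sum((coords / inner_ax) ** 2, axis=-1)
    head = r_outer <= 1.0
    soft = r_inner <= 1.0
    shell = head & ~soft

    hu = np.full(geom.shape, spec.background_hu)
    hu[soft] = spec.soft_tissue_hu
    hu[shell] = spec.bone_hu

    masks = {
        "head": SegmentationMask(head, geom, "head"),
        "bone": SegmentationMask(shell, geom, "bone"),
    }
    for n, (center, radius, tumor_hu) in enumerate(spec.tumors):
        if tumor_hu > spec.native_max_hu:
            raise PhantomSpecError(f"tumor HU {tumor_hu} exceeds the native ceiling")
        d2 = np.sum((coords - np.asarray(center, float)) ** 2, axis=-1)
        tmask = d2 <= float(radius) ** 2
        hu[tmask] = tumor_hu
        masks[f"tumor_{n}"] = SegmentationMask(tmask, geom, f"tumor_{n}")

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_hu > 0:
        noise = np.rint(rng.normal(0.0, spec.noise_sigma_hu, size=geom.shape))
        hu[head] += noise[head]

    fid_pts = np.asarray(spec.fiducials, dtype=float)
    for center in fid_pts:
        d2 = np.sum((coords - center) ** 2, axis=-1)
        hu[d2 <= spec.fiducial_radius_mm**2] = spec.fiducial_hu

    np.clip(hu, -1024.0, spec.native_max_hu, out=hu)

    volume = CTVolume(
        intensities=hu,
        geometry=geom,
        rescale_slope=1.0,
        rescale_intercept=-1024.0,
        bits_stored=12,
        pixel_representation=0,
        source_metadata=None,
    )
    labels = tuple(f"screw_{n + 1}" for n in range(len(fid_pts)))
    fiducials = FiducialSet(labels, fid_pts.copy(), fid_pts.copy())
    return Phantom(volume=volume, fiducials=fiducials, masks=masks)


@dataclass(frozen=True)
class NavigationSimulation:
    """Simulated intraoperative session against a phantom.

    ``fiducials`` pairs noisy navigation-frame touch-offs with the exact
    image-frame marker positions; ``cloud`` holds the acquired points in
    the navigation frame; ``true_transform`` maps navigation -> image
    exactly; ``true_image_positions`` are the ground-truth image-frame
    specimen locations; ``histology_truth`` maps sequence numbers to the
    final histology result (for :func:`endicom.marking.classify_points`).
    """

    fiducials: FiducialSet
    cloud: PointCloud
    true_transform: RigidTransform
    true_image_positions: np.ndarray
    histology_truth: dict


def simulate_navigation(fids_true: FiducialSet, sigma_mm: float,
                        n_points: int, seed: int,
                        region_center=(18.0, 24.0, -10.0),
                        region_radius_mm: float = 10.0,
                        transform: RigidTransform | None = None,
                        p_malignant: float = 0.4,
                        p_benign: float = 0.4) -> NavigationSimulation:
    """Emulate registration touch-offs and specimen acquisition.

    A random rigid transform (image -> navigation) defines where the
    patient lies relative to the tracker; fiducial touch-offs get isotropic
    Gaussian noise with per-axis standard deviation ``sigma_mm``;
    ``n_points`` specimen locations are drawn uniformly from a ball
    (default: around the default tumor) and assigned malignant/benign/
    unknown with probabilities (``p_malignant``, ``p_benign``, remainder).
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    rng = np.random.default_rng(seed)
    img_to_nav = transform if transform is not None else random_rigid_transform(rng)
    nav_to_img = invert_transform(img_to_nav)

    nav_fids = apply_transform(img_to_nav, fids_true.image_points)
    nav_fids = nav_fids + rng.normal(0.0, sigma_mm, size=nav_fids.shape)
    noisy = FiducialSet(fids_true.labels, nav_fids, fids_true.image_points.copy())

    # uniform draws in a ball via rejection from the cube
    center = np.asarray(region_center, dtype=float)
    pts = np.empty((n_points, 3))
    n_have = 0
    while n_have < n_points:
        cand = rng.uniform(-1.0, 1.0, size=(max(8, 2 * n_points), 3))
        cand = cand[np.sum(cand**2, axis=1) <= 1.0]
        take = min(len(cand), n_points - n_have)
        pts[n_have:n_have + take] = center + region_radius_mm * cand[:take]
        n_have += take

    u = rng.random(n_points)
    histology = np.where(
        u < p_malignant, Histology.MALIGNANT.value,
        np.where(u < p_malignant + p_benign, Histology.BENIGN.value,
                 Histology.UNKNOWN.value))
    nav_positions = apply_transform(img_to_nav, pts)
    points = tuple(
        AcquiredPoint(name=f"specimen_{n + 1}", sequence_number=n + 1,
                      position=nav_positions[n])
        for n in range(n_points)
    )
    truth = {n + 1: histology[n] for n in range(n_points)
             if histology[n] != Histology.UNKNOWN.value}
    return NavigationSimulation(
        fiducials=noisy,
        cloud=PointCloud(points, Frame.NAVIGATION),
        true_transform=nav_to_img,
        true_image_positions=pts,
        histology_truth=truth,
    )
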