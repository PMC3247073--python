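"""Landmark-based rigid fusion: resample one CT volume into another's frame.

Superimposing the marked (enhanced) data set with a post-operative scan
requires resampling the source volume onto the target lattice after a
rigid transform estimated from fiducial or anatomical landmark pairs.

Sentinel marks need special care under resampling: trilinear interpolation
would smear a 3500 HU single-voxel mark across its neighbors and below the
extraction threshold — the one failure mode that would silently destroy
the encoded information. Voxels whose nearest source sample is in the
sentinel band are therefore always resampled nearest-neighbor, whatever
interpolation the rest of the volume uses. The lossless alternative, when
the point table is available, is :func:`fuse_points`, which maps the
points themselves and never touches voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .dicom_io import CTVolume, widen_for_hu
from .geometry import voxel_grid_patient_coords
from .marking import Frame, PointCloud
from .registration import RigidTransform, apply_transform, invert_transform

__all__ = ["FusionResult", "fuse", "fuse_points"]


@dataclass(frozen=True)
class FusionResult:
    """Source volume resampled onto the target lattice."""

    resampled: CTVolume  # geometry == target geometry
    transform: RigidTransform  # source -> target frame
    interpolation: str


def fuse(source: CTVolume, target: CTVolume, transform: RigidTransform,
         interp: str = "trilinear", fill_hu: float = -1024.0,
         sentinel_threshold_hu: float = 3200.0) -> FusionResult:
    """Resample ``source`` onto ``target``'s lattice under a rigid transform.

    Parameters
    ----------
    transform
        Maps source patient frame to target patient frame.
    interp
        ``"nearest"`` or ``"trilinear"``. Trilinear output is rounded to
        integer HU so the result remains representable as stored pixels.
    fill_hu
        Value for target voxels that sample outside the source volume.
    sentinel_threshold_hu
        Voxels whose nearest source sample is at or above this value are
        taken nearest-neighbor regardless of ``interp`` (mark protection).
    """
    if interp not in ("nearest", "trilinear"):
        raise ValueError("interp must be 'nearest' or 'trilinear'")
    tgt_geom = target.geometry
    src_geom = source.geometry

    coords = voxel_grid_patient_coords(tgt_geom).reshape(-1, 3)
    src_points = apply_transform(invert_transform(transform), coords)
    d = src_geom._index_to_mm / np.sum(src_geom._index_to_mm**2, axis=0)
    cont = ((src_points - src_geom.origin) @ d).T  # (3, n) fractional (k, i, j)

    nearest = ndimage.map_coordinates(source.intensities, cont, order=0,
                                      mode="constant", cval=fill_hu)
    if interp == "nearest":
        out = nearest
    else:
        out = ndimage.map_coordinates(source.intensities, cont, order=1,
                                      mode="constant", cval=fill_hu)
        protect = nearest >= sentinel_threshold_hu
        out[protect] = nearest[protect]
        out = np.rint(out)
    out = out.reshape(tgt_geom.shape)

    resampled = CTVolume(
        intensities=out,
        geometry=tgt_geom,
        rescale_slope=source.rescale_slope,
        rescale_intercept=source.rescale_intercept,
        bits_stored=source.bits_stored,
        pixel_representation=source.pixel_representation,
        source_metadata=None,
    )
    top = float(out.max()) if out.size else 0.0
    resampled = widen_for_hu(resampled, max(top, fill_hu))
    return FusionResult(resampled=resampled, transform=transform,
                        interpolation=interp)


def fuse_points(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Map an image-frame point cloud into the target frame losslessly.

    The exact counterpart of voxel-level fusion: no resampling, no
    quantization — positions are simply transformed.
    """
    if cloud.frame is not Frame.IMAGE:
        raise ValueError("fuse_points expects an image-frame cloud")
    new_points = tuple(
        replace(p, position=apply_transform(transform, p.position))
        for p in cloud
    )
    return PointCloud(new_points, Frame.IMAGE)
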