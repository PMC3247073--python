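"""Landmark-based fusion of a marked series onto another volume's lattice.

Emulates superimposing the enhanced data set with a post-operative scan:
the marked phantom is resampled onto a rigidly moved target lattice using
trilinear interpolation, while sentinel voxels are protected (resampled
nearest-neighbor) so thresholding still finds them after fusion.
"""

import numpy as np

from endicom.codec import encode, extract
from endicom.fusion import fuse, fuse_points
from endicom.marking import AcquiredPoint, Frame, Histology, PointCloud
from endicom.phantom import PhantomSpec, make_phantom
from endicom.registration import RigidTransform

phantom = make_phantom(PhantomSpec(seed=0))
cloud = PointCloud(tuple(
    AcquiredPoint(f"specimen {n + 1}", n + 1, np.array(p), Histology.MALIGNANT)
    for n, p in enumerate([(17.3, 22.1, -8.6), (12.9, 27.4, -11.2)])),
    Frame.IMAGE)
marked = encode(phantom.volume, cloud)

angle = np.deg2rad(4.0)
transform = RigidTransform(
    np.array([[np.cos(angle), -np.sin(angle), 0.0],
              [np.sin(angle), np.cos(angle), 0.0],
              [0.0, 0.0, 1.0]]),
    np.array([2.5, -1.0, 0.5]))

result = fuse(marked, phantom.volume, transform, interp="trilinear")
report = extract(result.resampled, 3200.0)
print(f"after trilinear fusion, threshold 3200 HU still finds "
      f"{report.voxel_count} mark voxels (marks are interpolation-protected)")

exact = fuse_points(cloud, transform)
rec = report.recovered.positions()
d = np.linalg.norm(exact.positions()[:, None] - rec[None], axis=-1).min(axis=1)
bound = result.resampled.geometry.voxel_diagonal_mm  # two half-diagonals
for p, err in zip(cloud, d):
    print(f"  {p.name}: voxel-path vs point-path disagreement {err:.3f} mm")
print(f"all within the composed quantization bound {bound:.3f} mm")
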