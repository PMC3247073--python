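"""Mark tumor-positive points as sentinel voxels and recover them by threshold.

Builds the default synthetic head phantom, encodes three confirmed
tumor-positive specimen locations at 3500 HU, and recovers them with a
3200 HU threshold. The printed distances are the quantization cost of
rounding each point to its nearest voxel center — never more than half the
voxel diagonal (0.87 mm on this 1 mm grid).
"""

import numpy as np

from endicom.codec import encode, extract, roundtrip_error
from endicom.marking import AcquiredPoint, Frame, Histology, PointCloud
from endicom.phantom import PhantomSpec, make_phantom

phantom = make_phantom(PhantomSpec(seed=0))
volume = phantom.volume
print(f"phantom: {volume.geometry.shape} voxels, "
      f"native max {volume.intensities.max():.0f} HU")

points = PointCloud(tuple(
    AcquiredPoint(name, n + 1, np.array(pos), Histology.MALIGNANT)
    for n, (name, pos) in enumerate([
        ("margin lateral", (17.3, 22.1, -8.6)),
        ("margin medial", (12.9, 27.4, -11.2)),
        ("frozen section 3", (21.0, 20.0, -6.0)),
    ])), Frame.IMAGE)

marked = encode(volume, points)
changed = int((marked.intensities != volume.intensities).sum())
print(f"encoded {len(points)} points -> {changed} voxels at 3500 HU "
      f"(bit depth widened to {marked.bits_stored})")

report = extract(marked, threshold_hu=3200.0)
print(f"threshold 3200 HU recovers {report.voxel_count} voxels")
rt = roundtrip_error(points, report, volume.geometry)
for p, d in zip(points, rt.distances_mm):
    print(f"  {p.name:18s} quantization error {d:.3f} mm")
print(f"max error {rt.max_mm:.3f} mm <= half voxel diagonal "
      f"{volume.geometry.voxel_diagonal_mm / 2:.3f} mm")
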