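"""The five-step marking workflow as one library call.

register (gate on RMS) -> transform acquired points into the image frame ->
select confirmed tumor-positive points -> encode them as sentinel voxels ->
write the enhanced series plus the sidecar point table, with a
machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import codec, dicom_io, marking, registration
from .errors import EndicomError

__all__ = ["WorkflowConfig", "RunReport", "GateFailure", "run_workflow"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkflowConfig:
    """All tunables of a workflow run; serializable to a JSON text file."""

    sentinel_hu: float = 3500.0
    native_max_hu: float = 3100.0
    extraction_threshold_hu: float = 3200.0
    rms_gate_mm: float = 0.8
    margin_mm: float = 10.0
    interpolation: str = "trilinear"
    mark_radius_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.native_max_hu < self.extraction_threshold_hu <= self.sentinel_hu:
            raise ValueError(
                "require native_max_hu < extraction_threshold_hu <= sentinel_hu "
                f"(got {self.native_max_hu}, {self.extraction_threshold_hu}, "
                f"{self.sentinel_hu})")
        if self.rms_gate_mm <= 0 or self.margin_mm < 0:
            raise ValueError("rms_gate_mm must be > 0 and margin_mm >= 0")

    @classmethod
    def from_file(cls, path) -> "WorkflowConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    def encoding_policy(self) -> codec.EncodingPolicy:
        return codec.EncodingPolicy(
            sentinel_hu=self.sentinel_hu,
            max_native_hu=self.native_max_hu,
            mark_radius_mm=self.mark_radius_mm,
        )


class GateFailure(EndicomError):
    """Registration RMS exceeded the acceptance gate."""

    def __init__(self, report: registration.GateReport):
        super().__init__(str(report))
        self.report = report


@dataclass(frozen=True)
class RunReport:
    rms_error_mm: float
    gate_passed: bool
    gate_threshold_mm: float
    n_acquired: int
    n_malignant: int
    marked_voxel_count: int
    output_series: str
    output_points: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def run_workflow(config: WorkflowConfig, series_dir, fiducial_file, points_file,
                 out_dir, force: bool = False) -> RunReport:
    """Run the full marking pipeline on files; see module docstring.

    Raises :class:`GateFailure` (and writes nothing) when the registration
    RMS exceeds ``config.rms_gate_mm``, unless ``force`` is set.
    """
    for name, value in dataclasses.asdict(config).items():
        logger.info("config %s = %r", name, value)

    volume = dicom_io.read_series(series_dir)
    fids = registration.load_fiducials(fiducial_file)
    cloud = marking.load_point_cloud(points_file)

    transform = registration.estimate_rigid(fids)
    gate = registration.registration_gate(transform, config.rms_gate_mm)
    logger.info("%s", gate)
    if not gate.passed and not force:
        raise GateFailure(gate)

    if cloud.frame is marking.Frame.NAVIGATION:
        cloud = marking.to_image_frame(cloud, transform)
    malignant = marking.select_malignant(cloud)
    logger.info("%d of %d points are confirmed tumor-positive",
                len(malignant), len(cloud))

    marked = codec.encode(volume, malignant, config.encoding_policy())
    changed = int((marked.intensities != volume.intensities).sum())

    out_dir = Path(out_dir)
    dicom_io.write_series(marked, out_dir)
    points_out = out_dir / "marked_points.csv"
    marking.save_point_cloud(malignant, points_out)

    report = RunReport(
        rms_error_mm=transform.rms_error,
        gate_passed=gate.passed,
        gate_threshold_mm=config.rms_gate_mm,
        n_acquired=len(cloud),
        n_malignant=len(malignant),
        marked_voxel_count=changed,
        output_series=str(out_dir),
        output_points=str(points_out),
    )
    (out_dir / "run_report.json").write_text(report.to_json())
    return report
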