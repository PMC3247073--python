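"""Intraoperatively acquired landmark points and their histology workflow.

Each specimen location (biopsy, frozen section, resection margin) is
recorded as a named, sequentially numbered point in the navigation frame.
After the final histopathology report the points are classified
benign/malignant; only confirmed tumor-positive points are selected for
export, since a false-positive mark would corrupt downstream radiotherapy
planning. Clouds are immutable: every operation returns a new cloud.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._tables import read_table
from .errors import FrameError, UnknownSequenceError
from .registration import RigidTransform, apply_transform

__all__ = [
    "Histology",
    "Frame",
    "AcquiredPoint",
    "PointCloud",
    "acquire_point",
    "classify_points",
    "select_malignant",
    "to_image_frame",
    "load_point_cloud",
    "save_point_cloud",
]


class Histology(str, enum.Enum):
    UNKNOWN = "unknown"
    BENIGN = "benign"
    MALIGNANT = "malignant"


class Frame(str, enum.Enum):
    NAVIGATION = "navigation"
    IMAGE = "image"


@dataclass(frozen=True)
class AcquiredPoint:
    """A single recorded specimen location.

    ``sequence_number`` follows acquisition order (1-based) and is the key the
    pathology report refers back to; ``histology`` stays ``UNKNOWN`` until the
    final report is released.
    """

    name: str
    sequence_number: int
    position: np.ndarray  # (3,) mm
    histology: Histology = Histology.UNKNOWN

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector (mm)")
        if self.sequence_number < 1:
            raise ValueError("sequence_number must be a positive integer")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "histology", Histology(self.histology))
        object.__setattr__(self, "sequence_number", int(self.sequence_number))


@dataclass(frozen=True)
class PointCloud:
    """Ordered collection of acquired points in one coordinate frame."""

    points: tuple[AcquiredPoint, ...] = ()
    frame: Frame = Frame.NAVIGATION

    def __post_init__(self):
        pts = tuple(self.points)
        seqs = [p.sequence_number for p in pts]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise ValueError("sequence numbers must be strictly increasing")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "frame", Frame(self.frame))

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions in acquisition order."""
        if not self.points:
            return np.empty((0, 3))
        return np.stack([p.position for p in self.points])

    def by_sequence(self, sequence_number: int) -> AcquiredPoint:
        for p in self.points:
            if p.sequence_number == sequence_number:
                return p
        raise UnknownSequenceError(sequence_number)


def acquire_point(cloud: PointCloud, name: str, position) -> PointCloud:
    """Append a newly recorded point with the next sequence number.

    Acquisition happens in the navigation frame; histology starts unknown.
    Coincident positions with different names are legitimate (adjacent
    specimens can be sampled at the same tracked location).
    """
    if cloud.frame is not Frame.NAVIGATION:
        raise FrameError("points are acquired in the navigation frame")
    next_seq = cloud.points[-1].sequence_number + 1 if cloud.points else 1
    point = AcquiredPoint(name=name, sequence_number=next_seq, position=position)
    return PointCloud(cloud.points + (point,), cloud.frame)


def classify_points(cloud: PointCloud, results: dict) -> PointCloud:
    """Attach final histology results, keyed by sequence number.

    Points absent from ``results`` keep their current histology (typically
    unknown). A result for a sequence number not in the cloud is an error —
    it would mean a specimen label mismatch.
    """
    known = {p.sequence_number for p in cloud.points}
    for seq in results:
        if seq not in known:
            raise UnknownSequenceError(
                f"histology result for sequence number {seq} which is not in the cloud")
    new_points = tuple(
        replace(p, histology=Histology(results[p.sequence_number]))
        if p.sequence_number in results else p
        for p in cloud.points
    )
    return PointCloud(new_points, cloud.frame)


def select_malignant(cloud: PointCloud) -> PointCloud:
    """Sub-cloud of confirmed tumor-positive points, sequence numbers kept.

    Unknown histology is deliberately excluded: only points the pathologist
    confirmed malignant may be exported into the planning data set.
    """
    return PointCloud(
        tuple(p for p in cloud.points if p.histology is Histology.MALIGNANT),
        cloud.frame,
    )


def to_image_frame(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Map a navigation-frame cloud into the image frame via the registration
    transform (navigation -> image)."""
    if cloud.frame is Frame.IMAGE:
        raise FrameError("cloud is already in the image frame")
    new_points = tuple(
        replace(p, position=apply_transform(transform, p.position))
        for p in cloud.points
    )
    return PointCloud(new_points, Frame.IMAGE)


POINT_COLUMNS = ["sequence", "name", "x", "y", "z", "histology", "frame"]


def save_point_cloud(cloud: PointCloud, path) -> None:
    """Write the flat point table: sequence, name, x, y, z, histology, frame.

    Full float precision so save/load round-trips losslessly.
    """
    df = pd.DataFrame({
        "sequence": [p.sequence_number for p in cloud.points],
        "name": [p.name for p in cloud.points],
        "x": [p.position[0] for p in cloud.points],
        "y": [p.position[1] for p in cloud.points],
        "z": [p.position[2] for p in cloud.points],
        "histology": [p.histology.value for p in cloud.points],
        "frame": [cloud.frame.value] * len(cloud.points),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def load_point_cloud(path) -> PointCloud:
    df = read_table(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point table {path} missing columns: {missing}")
    frames = set(df["frame"].astype(str)) or {Frame.NAVIGATION.value}
    if len(frames) > 1:
        raise FrameError(f"point table mixes frames: {sorted(frames)}")
    points = tuple(
        AcquiredPoint(
            name=str(row["name"]),
            sequence_number=int(row["sequence"]),
            position=np.array([row["x"], row["y"], row["z"]], dtype=float),
            histology=Histology(str(row["histology"])),
        )
        for _, row in df.iterrows()
    )
    frame = Frame(frames.pop()) if points else Frame.NAVIGATION
    return PointCloud(points, frame)
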