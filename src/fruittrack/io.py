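"""Detection and track file I/O.

Detections arrive as per-frame axis-aligned bounding boxes in a small CSV
dialect (``frame,left,top,width,height[,confidence]``) that any detector can
emit.  Tracker output is written as ``frame,track_id,left,top,width,height,
status`` where status records whether the box came from a real detection or
from the motion model's prediction.

Coordinate convention: pixels, origin at the image top-left, x rightward,
y downward; frame indices are 0-based.  Boxes are stored as
(left, top, width, height); centre points are always derived, never stored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Detection",
    "TrackRecord",
    "DetectionParseError",
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "centroid",
    "size_filter",
]

DETECTION_HEADER = ("frame", "left", "top", "width", "height", "confidence")
TRACK_HEADER = ("frame", "track_id", "left", "top", "width", "height", "status")

#: Track-record status values.
STATUS_DETECTED = "detected"
STATUS_PREDICTED = "predicted"


class DetectionParseError(ValueError):
    """Raised for malformed detection/track rows; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Detection:
    """One bounding box in one frame.

    Parameters
    ----------
    frame : int
        0-based frame index, >= 0.
    left, top : float
        Top-left corner of the box in pixels.
    width, height : float
        Box size in pixels; must be > 0.
    confidence : float, optional
        Detector score in [0, 1].  Read for provenance but not used by the
        tracker (score thresholding and NMS belong inside the detector).
    """

    frame: int
    left: float
    top: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self):
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box size must be positive, got width={self.width} height={self.height}"
            )

    @property
    def centre(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)


@dataclass(frozen=True)
class TrackRecord:
    """One track's registered box in one frame.

    ``status`` is ``"detected"`` when the box is the assigned detection and
    ``"predicted"`` when the position was registered from the motion model
    (box size then carries the last known size).  ``det_row`` is the 0-based
    row of the consumed detection within its frame (in-memory provenance
    only; not serialized).
    """

    frame: int
    track_id: int
    left: float
    top: float
    width: float
    height: float
    status: str
    det_row: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.status not in (STATUS_DETECTED, STATUS_PREDICTED):
            raise ValueError(f"unknown status {self.status!r}")


def centroid(d: Detection) -> tuple[float, float]:
    """Centre point (x, y) of a detection's bounding box in pixels."""
    return d.centre


def _parse_float(text: str, what: str, line: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise DetectionParseError(f"cannot parse {what} from {text!r}", line) from None


def read_detections(
    path: str | Path, dialect: str = "csv"
) -> dict[int, list[Detection]]:
    """Read per-frame detections from a CSV file.

    Returns a dict mapping every frame index in ``0..max_frame`` to its
    (possibly empty) list of detections; within a frame, file order is
    preserved.  An optional header row is recognised and skipped.  An empty
    file yields an empty dict.

    Raises
    ------
    DetectionParseError
        For a malformed row (names the line number) or a non-positive box.
    """
    if dialect != "csv":
        raise ValueError(f"unknown detection dialect {dialect!r}")
    path = Path(path)
    detections: list[Detection] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "frame":
                continue
            if len(row) not in (5, 6):
                raise DetectionParseError(
                    f"expected 5 or 6 fields, got {len(row)}", lineno
                )
            try:
                frame = int(row[0])
            except ValueError:
                raise DetectionParseError(
                    f"cannot parse frame index from {row[0]!r}", lineno
                ) from None
            left = _parse_float(row[1], "left", lineno)
            top = _parse_float(row[2], "top", lineno)
            width = _parse_float(row[3], "width", lineno)
            height = _parse_float(row[4], "height", lineno)
            conf = _parse_float(row[5], "confidence", lineno) if len(row) == 6 else 1.0
            try:
                det = Detection(frame, left, top, width, height, conf)
            except ValueError as exc:
                raise DetectionParseError(str(exc), lineno) from None
            detections.append(det)
    return group_by_frame(detections)


def group_by_frame(detections: Iterable[Detection]) -> dict[int, list[Detection]]:
    """Group detections by frame, filling empty frames over ``0..max_frame``."""
    dets = list(detections)
    if not dets:
        return {}
    n_frames = max(d.frame for d in dets) + 1
    frames: dict[int, list[Detection]] = {k: [] for k in range(n_frames)}
    for d in dets:
        frames[d.frame].append(d)
    return frames


def write_detections(frames: Mapping[int, Sequence[Detection]], path: str | Path) -> None:
    """Write detections back to the CSV dialect read by :func:`read_detections`."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTION_HEADER)
        for frame in sorted(frames):
            for d in frames[frame]:
                writer.writerow(
                    [d.frame, _fmt(d.left), _fmt(d.top), _fmt(d.width), _fmt(d.height), _fmt(d.confidence)]
                )


def _fmt(x: float) -> str:
    # repr round-trips floats exactly; integers print without trailing ".0"
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def size_filter(
    detections: Sequence[Detection],
    min_width: float = 12.0,
    min_height: float = 15.0,
) -> list[Detection]:
    """Drop boxes smaller than the far-side-fruit size threshold.

    Fruit on the far side of the canopy (seen through the tree from the other
    inter-row) image smaller; excluding boxes with width < ``min_width`` or
    height < ``min_height`` suppresses most cross-row double counting.  Boxes
    exactly at the thresholds are kept.  Order is preserved; the operation is
    idempotent.
    """
    if min_width < 0 or min_height < 0:
        raise ValueError("size thresholds must be >= 0")
    return [d for d in detections if d.width >= min_width and d.height >= min_height]


def write_tracks(records: Iterable[TrackRecord], path: str | Path) -> None:
    """Write track records as ``frame,track_id,left,top,width,height,status`` CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACK_HEADER)
        for r in records:
            writer.writerow(
                [r.frame, r.track_id, _fmt(r.left), _fmt(r.top), _fmt(r.width), _fmt(r.height), r.status]
            )


def read_tracks(path: str | Path) -> list[TrackRecord]:
    """Read track records written by :func:`write_tracks` (field-exact round trip)."""
    records: list[TrackRecord] = []
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "frame":
                continue
            if len(row) != 7:
                raise DetectionParseError(f"expected 7 fields, got {len(row)}", lineno)
            try:
                records.append(
                    TrackRecord(
                        frame=int(row[0]),
                        track_id=int(row[1]),
                        left=float(row[2]),
                        top=float(row[3]),
                        width=float(row[4]),
                        height=float(row[5]),
                        status=row[6],
                    )
                )
            except ValueError as exc:
                raise DetectionParseError(str(exc), lineno) from None
    return records
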