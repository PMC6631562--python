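"""Frame-by-frame tracking workflow and cumulative fruit count.

Per frame: size-filter the detections, associate them with live tracks
(two-pass gated Hungarian), Kalman-update the matched tracks, propagate the
unmatched ones (predicted position, or an artificial borrowed-speed update
for unstable tracks), drop tracks unobserved for more than ``max_unobserved``
consecutive frames, and open a new track for every unclaimed detection.  The
fruit count is the number of distinct track identities ever created — a
fruit re-detected within the retention window at its predicted position
keeps its identity and is not recounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import io as fio
from .assignment import improved_assignment
from .kalman import MotionModel, Track, init_track, nearest_stable_speed

__all__ = ["TrackerConfig", "TrackerState", "CountReport", "Tracker", "run"]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable parameters of the tracking workflow.

    max_unobserved : frames a track survives without a valid assignment
        (the retention window; a fruit reappearing on-trajectory within it
        keeps its identity).
    distance_threshold : gating distance in pixels for a valid assignment.
    min_width / min_height : pre-tracking size filter (px); boxes smaller on
        either side are treated as far-side fruit and discarded.
    default_speed : global (vx, vy) in px/frame used before any stable track
        exists, matching the nominal platform shift.
    stability_min_updates : real measurements needed before a track's own
        motion model is trusted.
    q, r, p0, dt : Kalman scalars (process noise, measurement noise, initial
        covariance, frame interval).
    """

    max_unobserved: int = 15
    distance_threshold: float = 60.0
    min_width: float = 12.0
    min_height: float = 15.0
    default_speed: tuple[float, float] = (20.0, 0.0)
    stability_min_updates: int = 4
    q: float = 1.0
    r: float = 0.1
    p0: float = 10.0
    dt: float = 1.0

    def __post_init__(self):
        if self.max_unobserved < 0:
            raise ValueError("max_unobserved must be >= 0")
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be > 0")

    @property
    def motion_model(self) -> MotionModel:
        return MotionModel(dt=self.dt, q=self.q, r=self.r)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "TrackerConfig":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in mapping and mapping[f] is not None:
                v = mapping[f]
                kwargs[f] = tuple(v) if f == "default_speed" else v
        return cls(**kwargs)


@dataclass
class FrameSummary:
    frame: int
    live: int
    detected: int
    predicted: int
    created: int


@dataclass
class CountReport:
    """Result of a full tracking run.

    total : distinct track identities created = estimated fruit count.
    frames : number of frames processed.
    per_frame : per-frame live/detected/predicted/created summaries.
    records : per-frame registered boxes for every live track, with
        detection-row provenance on detected records.
    """

    total: int
    frames: int
    per_frame: list[FrameSummary] = field(default_factory=list)
    records: list[fio.TrackRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "frames": self.frames,
            "per_frame": [asdict(s) for s in self.per_frame],
        }


class TrackerState:
    """Mutable tracker state between frames."""

    def __init__(self):
        self.live_tracks: list[Track] = []
        self.next_id: int = 0
        self.total_created: int = 0
        self.frame_cursor: int = -1

    def issue_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        self.total_created += 1
        return i


class Tracker:
    """Streaming tracker; feed frames in increasing order via :meth:`step`."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.state = TrackerState()
        # stability threshold is configurable; patch the module constant per
        # track via each Track's update_count comparison
        self._stability = self.config.stability_min_updates

    # ------------------------------------------------------------------
    def _stable_tracks(self) -> list[Track]:
        return [t for t in self.state.live_tracks if t.update_count >= self._stability]

    def step(
        self, frame: int, detections: Sequence[fio.Detection]
    ) -> list[fio.TrackRecord]:
        """Process one frame's detections; returns this frame's track records."""
        s, cfg = self.state, self.config
        if frame <= s.frame_cursor:
            raise ValueError(
                f"frames must be presented in increasing order "
                f"(got {frame} after {s.frame_cursor})"
            )
        model = cfg.motion_model

        # (1) size filter: drop far-side fruit
        kept = fio.size_filter(detections, cfg.min_width, cfg.min_height)
        det_rows = [i for i, d in enumerate(detections)
                    if d.width >= cfg.min_width and d.height >= cfg.min_height]
        centres = [d.centre for d in kept]

        # (2) gated two-pass assignment against registered positions
        positions = [t.position for t in s.live_tracks]
        result = improved_assignment(positions, centres, cfg.distance_threshold)

        records: list[fio.TrackRecord] = []
        assigned_tracks: dict[int, int] = {ti: dj for ti, dj, _ in result.pairs}

        # (3) matched tracks: Kalman update with the detection centre
        for ti, dj in assigned_tracks.items():
            t = s.live_tracks[ti]
            d = kept[dj]
            t.update(d.centre, model, frame=frame)
            t.last_box = (d.width, d.height)
            records.append(
                fio.TrackRecord(
                    frame=frame, track_id=t.id,
                    left=d.left, top=d.top, width=d.width, height=d.height,
                    status=fio.STATUS_DETECTED, det_row=det_rows[dj],
                )
            )

        # (4) unmatched tracks: predicted position / borrowed-speed update
        stable = self._stable_tracks()
        for ti in result.unassigned_tracks:
            t = s.live_tracks[ti]
            if t.update_count >= self._stability:
                t.coast(model)
            else:
                speed = nearest_stable_speed(
                    t.position, stable, cfg.default_speed, exclude_id=t.id
                )
                z = t.position + np.asarray(speed)
                t.update(z, model, artificial=True)
            x, y = t.position
            w, h = t.last_box
            records.append(
                fio.TrackRecord(
                    frame=frame, track_id=t.id,
                    left=x - w / 2.0, top=y - h / 2.0, width=w, height=h,
                    status=fio.STATUS_PREDICTED,
                )
            )

        # (5) prune tracks unobserved beyond the retention window
        s.live_tracks = [
            t for t in s.live_tracks if t.unobserved_count <= cfg.max_unobserved
        ]

        # (6) unclaimed detections become new tracks (ids in detection order),
        # borrowing an initial speed from the nearest stable track
        stable = self._stable_tracks()
        for dj in result.unassigned_detections:
            d = kept[dj]
            speed = nearest_stable_speed(d.centre, stable, cfg.default_speed)
            t = init_track(d, speed, s.issue_id(), p0=cfg.p0)
            s.live_tracks.append(t)
            records.append(
                fio.TrackRecord(
                    frame=frame, track_id=t.id,
                    left=d.left, top=d.top, width=d.width, height=d.height,
                    status=fio.STATUS_DETECTED, det_row=det_rows[dj],
                )
            )

        s.frame_cursor = frame
        records.sort(key=lambda r: r.track_id)
        return records


def run(
    detection_stream: Mapping[int, Sequence[fio.Detection]] | Iterable[Sequence[fio.Detection]],
    cfg: TrackerConfig | None = None,
) -> CountReport:
    """Track a whole detection stream and count distinct fruit.

    ``detection_stream`` is either a mapping frame->detections (as returned
    by :func:`fruittrack.io.read_detections`) or an iterable of per-frame
    detection lists taken as frames 0, 1, 2, ...
    """
    cfg = cfg or TrackerConfig()
    tracker = Tracker(cfg)
    if isinstance(detection_stream, Mapping):
        items = [(k, detection_stream[k]) for k in sorted(detection_stream)]
    else:
        items = list(enumerate(detection_stream))

    report = CountReport(total=0, frames=len(items))
    for frame, dets in items:
        created_before = tracker.state.total_created
        records = tracker.step(frame, dets)
        report.records.extend(records)
        detected = sum(1 for r in records if r.status == fio.STATUS_DETECTED)
        report.per_frame.append(
            FrameSummary(
                frame=frame,
                live=len(tracker.state.live_tracks),
                detected=detected,
                predicted=len(records) - detected,
                created=tracker.state.total_created - created_before,
            )
        )
    report.total = tracker.state.total_created
    return report
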