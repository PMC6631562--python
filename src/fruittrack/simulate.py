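"""Synthetic orchard detection streams with ground truth.

Emulates the acquisition geometry of a night-imaging platform driving along
an orchard inter-row: 1024x1024 frames, content shifting ~20 px/frame
horizontally (10 fps at ~5 km/h), on the order of 31 fruit visible per
frame, and a detector that misses ~1.4 fruit per frame and hallucinates
~1.4 boxes per frame.  Platform oscillation enters as small per-frame camera
rotation and scale jitter about the image centre, so fruit far from the
centre move more than fruit near it — exactly the disturbance the tracker's
process noise must absorb.

Fruit live on a static world strip; the camera window slides along it so
that image content moves in +x and new fruit enter at the left edge.  Every
emitted detection carries provenance (its fruit id, or false positive), and
the ground truth records *why* a fruit went undetected in a frame (out of
frame, occluded, or a simulated detector miss), which is what lets the
evaluation module attribute double counts to causes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Detection

__all__ = ["SceneConfig", "Scene", "GroundTruth", "FrameStatus",
           "generate_scene", "project", "render_detections", "simulate"]

FALSE_POSITIVE = -1  # provenance label for hallucinated detections


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic acquisition run.

    Defaults reproduce the target geometry: 1024x1024 frames and a 20
    px/frame horizontal shift.  Detector error rates default to zero so the
    baseline scene is noiseless; the field-condition rates (fp_rate=1.4
    per frame and ~1.4 misses per frame, i.e. fn_prob~1.4/31 per fruit) are
    opted into per experiment.
    """

    n_frames: int = 110
    frame_size: tuple[int, int] = (1024, 1024)  # (width, height)
    shift_per_frame: float = 20.0
    n_fruit: int = 50
    fruit_size_range: tuple[float, float] = (20.0, 60.0)
    small_fruit_fraction: float = 0.0  # far-side fruit, width < 12 px
    rotation_jitter_sd: float = 0.0  # degrees/frame
    scale_jitter_sd: float = 0.0  # fraction/frame
    position_noise_sd: float = 0.0  # px on detection centres
    fp_rate: float = 0.0  # mean false positives / frame
    fn_prob: float = 0.0  # per-fruit per-frame miss probability
    occlusion_rate: float = 0.0  # per-fruit per-frame occlusion onset prob
    mean_occlusion_len: float = 5.0  # frames (geometric)
    min_separation: float = 0.0  # px between fruit in the world strip
    seed: int = 0

    def __post_init__(self):
        for name in ("shift_per_frame", "fp_rate", "fn_prob", "occlusion_rate",
                     "position_noise_sd", "rotation_jitter_sd", "scale_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def world_length(self) -> float:
        """Length of the world strip swept by the camera window."""
        return (self.n_frames - 1) * self.shift_per_frame + self.frame_size[0]


@dataclass
class Scene:
    """Resolved scene: fruit world geometry plus the camera path."""

    config: SceneConfig
    fruit_world: np.ndarray  # (n_fruit, 2) world positions
    fruit_size: np.ndarray  # (n_fruit, 2) box (width, height)
    camera_offsets: np.ndarray  # (n_frames,) world x of the image left edge
    rotations: np.ndarray  # (n_frames,) degrees
    scales: np.ndarray  # (n_frames,)
    occlusions: dict[int, list[tuple[int, int]]]  # fruit -> [start, end) windows

    def occluded(self, fruit: int, frame: int) -> bool:
        return any(a <= frame < b for a, b in self.occlusions.get(fruit, ()))


@dataclass(frozen=True)
class FrameStatus:
    """Why a fruit did or did not produce a detection in one frame."""

    position: tuple[float, float]  # true image position (pre-noise)
    in_frame: bool
    occluded: bool
    fn_dropped: bool

    @property
    def visible(self) -> bool:
        return self.in_frame and not self.occluded

    @property
    def detected(self) -> bool:
        return self.visible and not self.fn_dropped


@dataclass
class GroundTruth:
    """Provenance for every emitted detection plus per-fruit frame history."""

    provenance: dict[int, list[int]] = field(default_factory=dict)
    # fruit id -> frame -> status
    fruit_frames: dict[int, dict[int, FrameStatus]] = field(default_factory=dict)

    def fruit_seen(self) -> list[int]:
        """Fruit ids that produced at least one detection."""
        out = []
        for fid, hist in self.fruit_frames.items():
            if any(st.detected for st in hist.values()):
                out.append(fid)
        return sorted(out)

    def visible_per_frame(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for hist in self.fruit_frames.values():
            for frame, st in hist.items():
                counts[frame] = counts.get(frame, 0) + int(st.visible)
        return counts


def project(
    world_point: Sequence[float],
    camera_offset: float,
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    frame_size: tuple[int, int] = (1024, 1024),
) -> np.ndarray:
    """World point -> image point under the camera pose.

    Translation by the camera offset, then rotation and scaling about the
    image centre (y-down convention: positive angles rotate x toward y).
    Rotation displaces points proportionally to their distance from the
    centre, mimicking platform oscillation.
    """
    c = np.array([frame_size[0] / 2.0, frame_size[1] / 2.0])
    p = np.asarray(world_point, dtype=float) - np.array([camera_offset, 0.0]) - c
    th = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return R @ p * scale + c


def generate_scene(cfg: SceneConfig) -> Scene:
    """Sample fruit placement, camera path and occlusion windows.

    Fruit world x is uniform over the swept strip so every fruit enters the
    view at some point; the camera window starts at the strip's right end
    and slides left, which makes image content move +x and new fruit appear
    at the image's left edge.  Occlusion windows start with probability
    ``occlusion_rate`` per visible frame and last a geometric number of
    frames with the configured mean.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    width, height = cfg.frame_size
    L = cfg.world_length

    # placement, optionally with a minimum pairwise separation
    positions = np.empty((cfg.n_fruit, 2))
    placed = 0
    attempts = 0
    while placed < cfg.n_fruit:
        cand = np.array([rng.uniform(0.0, L), rng.uniform(0.0, height)])
        if cfg.min_separation > 0 and placed:
            d = np.hypot(*(positions[:placed] - cand).T)
            if d.min() < cfg.min_separation:
                attempts += 1
                if attempts > 10000 * cfg.n_fruit:
                    raise ValueError("min_separation too large for scene density")
                continue
        positions[placed] = cand
        placed += 1

    sizes = np.empty((cfg.n_fruit, 2))
    lo, hi = cfg.fruit_size_range
    for i in range(cfg.n_fruit):
        if rng.random() < cfg.small_fruit_fraction:
            w = rng.uniform(6.0, 11.0)  # far-side fruit: below the 12 px gate
            h = rng.uniform(8.0, 14.0)
        else:
            w = rng.uniform(lo, hi)
            h = w * rng.uniform(1.0, 1.3)
        sizes[i] = (w, h)

    frames = np.arange(cfg.n_frames)
    offsets = (cfg.n_frames - 1 - frames) * cfg.shift_per_frame
    rotations = (rng.normal(0.0, cfg.rotation_jitter_sd, cfg.n_frames)
                 if cfg.rotation_jitter_sd > 0 else np.zeros(cfg.n_frames))
    scales = (1.0 + rng.normal(0.0, cfg.scale_jitter_sd, cfg.n_frames)
              if cfg.scale_jitter_sd > 0 else np.ones(cfg.n_frames))

    occlusions: dict[int, list[tuple[int, int]]] = {}
    if cfg.occlusion_rate > 0:
        for i in range(cfg.n_fruit):
            windows: list[tuple[int, int]] = []
            k = 0
            while k < cfg.n_frames:
                if rng.random() < cfg.occlusion_rate:
                    length = rng.geometric(1.0 / max(cfg.mean_occlusion_len, 1.0))
                    windows.append((k, min(k + int(length), cfg.n_frames)))
                    k += int(length)
                k += 1
            if windows:
                occlusions[i] = windows

    return Scene(
        config=cfg,
        fruit_world=positions,
        fruit_size=sizes,
        camera_offsets=offsets.astype(float),
        rotations=rotations,
        scales=scales,
        occlusions=occlusions,
    )


def render_detections(
    scene: Scene, rng: np.random.Generator | None = None
) -> tuple[dict[int, list[Detection]], GroundTruth]:
    """Turn a scene into a per-frame detection stream plus ground truth.

    Per frame: project every fruit; a fruit whose centre lies in the frame
    and is not occluded is visible; each visible fruit is dropped with
    probability ``fn_prob`` (a simulated detector miss), otherwise its
    centre is jittered by Gaussian position noise and emitted as a box.
    Poisson(``fp_rate``) false positives are appended at uniform positions
    with sizes drawn from the true fruit size distribution — so the size
    filter cannot trivially remove them.
    """
    cfg = scene.config
    if rng is None:
        # offset stream so placement and rendering draws are independent
        rng = np.random.default_rng(cfg.seed + 1_000_003)
    width, height = cfg.frame_size
    lo, hi = cfg.fruit_size_range

    frames: dict[int, list[Detection]] = {}
    truth = GroundTruth()
    truth.fruit_frames = {i: {} for i in range(cfg.n_fruit)}

    for k in range(cfg.n_frames):
        dets: list[Detection] = []
        prov: list[int] = []
        for i in range(cfg.n_fruit):
            p = project(
                scene.fruit_world[i],
                scene.camera_offsets[k],
                scene.rotations[k],
                scene.scales[k],
                cfg.frame_size,
            )
            in_frame = bool(0.0 <= p[0] < width and 0.0 <= p[1] < height)
            occl = scene.occluded(i, k)
            fn = False
            if in_frame and not occl:
                fn = bool(cfg.fn_prob > 0 and rng.random() < cfg.fn_prob)
                if not fn:
                    centre = p.copy()
                    if cfg.position_noise_sd > 0:
                        centre = centre + rng.normal(0.0, cfg.position_noise_sd, 2)
                    w, h = scene.fruit_size[i] * scene.scales[k]
                    dets.append(
                        Detection(k, centre[0] - w / 2.0, centre[1] - h / 2.0, w, h)
                    )
                    prov.append(i)
            truth.fruit_frames[i][k] = FrameStatus(
                position=(float(p[0]), float(p[1])),
                in_frame=in_frame,
                occluded=occl,
                fn_dropped=fn,
            )
        if cfg.fp_rate > 0:
            for _ in range(rng.poisson(cfg.fp_rate)):
                cx, cy = rng.uniform(0, width), rng.uniform(0, height)
                w = rng.uniform(lo, hi)
                h = w * rng.uniform(1.0, 1.3)
                dets.append(Detection(k, cx - w / 2.0, cy - h / 2.0, w, h))
                prov.append(FALSE_POSITIVE)
        frames[k] = dets
        truth.provenance[k] = prov
    return frames, truth


def simulate(cfg: SceneConfig) -> tuple[dict[int, list[Detection]], GroundTruth, Scene]:
    """Generate a scene and render it; convenience one-call entry point."""
    scene = generate_scene(cfg)
    frames, truth = render_detections(scene)
    return frames, truth, scene


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write detection provenance as CSV ``frame,detection_row,fruit_id|FP``."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("frame", "detection_row", "fruit_id"))
        for frame in sorted(truth.provenance):
            for row, fid in enumerate(truth.provenance[frame]):
                writer.writerow((frame, row, "FP" if fid == FALSE_POSITIVE else fid))


def read_truth(path: str | Path) -> dict[int, list[int]]:
    """Read the provenance CSV written by :func:`write_truth`."""
    prov: dict[int, list[int]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0] == "frame":
                continue
            frame, det_row, fid = int(row[0]), int(row[1]), row[2]
            prov.setdefault(frame, [])
            assert det_row == len(prov[frame]), "truth rows out of order"
            prov[frame].append(FALSE_POSITIVE if fid == "FP" else int(fid))
    return prov
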