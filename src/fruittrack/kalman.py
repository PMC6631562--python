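"""Per-fruit constant-velocity Kalman filtering.

Each tracked fruit carries a 4-state filter over (x, y, vx, vy) — image
position in pixels and inter-frame speed in pixels/frame — observed through
its position only.  Camera rotation and scale variation (platform
oscillation, changing camera-to-fruit distance) are absorbed as process
noise, which is why the process-noise covariance is kept relatively large
(q = 1.0) against a small measurement noise (r = 0.1): detections locate
fruit precisely, but the motion deviates from pure translation.

A filter is considered *stable* once it has received at least four real
measurement updates.  Fruit without a stable model that miss a detection are
propagated with an *artificial measurement*: the previous position advanced
by a velocity borrowed from the nearest stable neighbour (or a global
default speed when no stable track exists, as in the first frames).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Detection, centroid

__all__ = ["MotionModel", "Track", "init_track", "nearest_stable_speed"]

#: Number of real measurement updates after which a filter is "stable".
STABILITY_MIN_UPDATES = 4


@dataclass(frozen=True)
class MotionModel:
    """Constant-velocity transition/measurement model and its noise levels.

    dt is the frame interval (1 by default: consecutive video frames).
    Q = q.I4 and R = r.I2; the scalars are the only tunables.
    """

    dt: float = 1.0
    q: float = 1.0
    r: float = 0.1

    @property
    def F(self) -> np.ndarray:
        """4x4 state transition: position advances by velocity.dt."""
        F = np.eye(4)
        F[0, 2] = self.dt
        F[1, 3] = self.dt
        return F

    @property
    def H(self) -> np.ndarray:
        """2x4 measurement matrix selecting (x, y)."""
        return np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])

    @property
    def Q(self) -> np.ndarray:
        return self.q * np.eye(4)

    @property
    def R(self) -> np.ndarray:
        return self.r * np.eye(2)


class Track:
    """One hypothesized fruit: Kalman state plus lifecycle counters.

    Attributes
    ----------
    id : int
        Unique identity, issued in order of first appearance.
    state : ndarray, shape (4,)
        Current (x, y, vx, vy) estimate.  The position components are the
        track's *registered position* for this frame: the posterior after a
        real or artificial update, or the committed prediction for stable
        tracks that went unobserved.
    P : ndarray, shape (4, 4)
        State error covariance; symmetric PSD after every predict/update.
    update_count : int
        Number of real measurement updates received (>= 1; initialisation
        counts as the first measurement).  Artificial updates do not count.
    unobserved_count : int
        Consecutive frames without a valid assignment; reset to 0 by every
        real update, incremented otherwise.
    last_detected_frame : int
        Frame index of the most recent real detection.
    last_box : tuple(float, float)
        (width, height) of the most recent real detection, used to draw
        predicted boxes.
    """

    __slots__ = (
        "id",
        "state",
        "P",
        "update_count",
        "unobserved_count",
        "last_detected_frame",
        "last_box",
    )

    def __init__(
        self,
        id: int,
        state: np.ndarray,
        P: np.ndarray,
        update_count: int = 1,
        unobserved_count: int = 0,
        last_detected_frame: int = 0,
        last_box: tuple[float, float] = (0.0, 0.0),
    ):
        self.id = int(id)
        self.state = np.asarray(state, dtype=float).copy()
        self.P = np.asarray(P, dtype=float).copy()
        self.update_count = update_count
        self.unobserved_count = unobserved_count
        self.last_detected_frame = last_detected_frame
        self.last_box = last_box

    # ------------------------------------------------------------------
    @property
    def position(self) -> np.ndarray:
        """Registered (x, y) position for the current frame."""
        return self.state[:2].copy()

    @property
    def velocity(self) -> np.ndarray:
        return self.state[2:].copy()

    @property
    def stable(self) -> bool:
        """True once at least four real measurements have been absorbed."""
        return self.update_count >= STABILITY_MIN_UPDATES

    # ------------------------------------------------------------------
    def predict(self, m: MotionModel) -> tuple[np.ndarray, np.ndarray]:
        """A-priori prediction (state' = F.state, P' = F.P.F^T + Q).

        Pure: returns the predicted (state, P) without mutating the track
        or its counters.
        """
        F = m.F
        return F @ self.state, F @ self.P @ F.T + m.Q

    def update(
        self,
        z: Sequence[float],
        m: MotionModel,
        frame: int | None = None,
        artificial: bool = False,
    ) -> None:
        """Predict then absorb measurement z = (x, y).

        Real updates (artificial=False) increment ``update_count``, reset
        ``unobserved_count`` and stamp ``last_detected_frame``.  Artificial
        updates (fabricated from a borrowed speed) refine the state the same
        way but count as an unobserved frame and never advance the track
        toward stability.
        """
        state_prior, P_prior = self.predict(m)
        H, R = m.H, m.R
        S = H @ P_prior @ H.T + R  # innovation covariance
        K = P_prior @ H.T @ np.linalg.inv(S)
        residual = np.asarray(z, dtype=float) - H @ state_prior
        self.state = state_prior + K @ residual
        P = (np.eye(4) - K @ H) @ P_prior
        self.P = (P + P.T) / 2.0  # enforce exact symmetry against round-off
        if artificial:
            self.unobserved_count += 1
        else:
            self.update_count += 1
            self.unobserved_count = 0
            if frame is not None:
                self.last_detected_frame = frame

    def coast(self, m: MotionModel) -> None:
        """Commit the prediction as the registered position (no measurement).

        Used for stable tracks that went unobserved: the covariance grows by
        Q each frame, reflecting mounting uncertainty, and the unobserved
        counter advances.
        """
        self.state, self.P = self.predict(m)
        self.unobserved_count += 1

    def handle_unassigned(
        self,
        stable_tracks: Sequence["Track"],
        default_speed: tuple[float, float],
        m: MotionModel,
    ) -> None:
        """Propagate a track that received no valid assignment this frame.

        A stable track simply registers its predicted position.  An unstable
        track — whose own velocity estimate is not yet trustworthy — fabricates
        a measurement from the nearest stable neighbour's velocity,
        z = previous position + (vx, vy), and runs a normal update with it
        (falling back on ``default_speed`` when no stable track exists).
        Either way the frame counts as unobserved.
        """
        if self.stable:
            self.coast(m)
            return
        speed = nearest_stable_speed(self.position, stable_tracks, default_speed, exclude_id=self.id)
        z = self.position + np.asarray(speed, dtype=float)
        self.update(z, m, artificial=True)


def nearest_stable_speed(
    position: Sequence[float],
    tracks: Sequence[Track],
    default_speed: tuple[float, float],
    exclude_id: int | None = None,
) -> tuple[float, float]:
    """Velocity of the nearest track among ``tracks`` (assumed stable).

    Distance is Euclidean between registered positions; ties break toward
    the lower track id.  Falls back on ``default_speed`` when no candidate
    (other than ``exclude_id``) exists.
    """
    pos = np.asarray(position, dtype=float)
    best: tuple[float, int] | None = None
    best_speed = None
    for t in tracks:
        if t.id == exclude_id:
            continue
        key = (float(np.hypot(*(t.position - pos))), t.id)
        if best is None or key < best:
            best = key
            best_speed = (float(t.state[2]), float(t.state[3]))
    if best_speed is None:
        return (float(default_speed[0]), float(default_speed[1]))
    return best_speed


def init_track(
    d: Detection,
    speed: tuple[float, float],
    id: int,
    p0: float = 10.0,
) -> Track:
    """Create a track from a first detection.

    The state starts at the detection's box centre with the supplied speed
    (borrowed from a stable neighbour, or the global default such as the
    nominal 20 px/frame platform shift).  P0 = p0.I4 is diffuse enough that
    early measurements dominate while keeping gains well conditioned.
    """
    cx, cy = centroid(d)
    state = np.array([cx, cy, float(speed[0]), float(speed[1])])
    return Track(
        id=id,
        state=state,
        P=p0 * np.eye(4),
        update_count=1,
        unobserved_count=0,
        last_detected_frame=d.frame,
        last_box=(d.width, d.height),
    )
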