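"""Track-to-detection data association.

Fruit are matched between neighbouring frames purely by Euclidean distance
between the tracked fruit's registered position and the new detection's box
centre.  The classic Hungarian (linear assignment) solution is refined by a
second pass over the tracks it left unassigned, which may propose an
already-claimed detection (a *multiple-to-one* assignment); such conflicts
are resolved in favour of the smaller distance.  A distance gate rejects any
pairing farther than a threshold (60 px by default, against a nominal 20
px/frame platform shift).

The two-pass scheme fixes a failure mode of the plain global optimum: when a
tracked fruit vanishes just as a new fruit appears nearby, the single-pass
assignment can chain-shift every fruit one slot over, mis-updating two
motion models at once.  Gating breaks the chain and the second pass lets the
displaced track compete for its true detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["AssignmentResult", "build_cost_matrix", "solve_lap", "improved_assignment"]


@dataclass
class AssignmentResult:
    """Validated pairs plus leftovers for one frame transition.

    pairs : list of (track_index, detection_index, distance)
        Each track index and detection index appears at most once and every
        distance is <= the gating threshold.
    unassigned_tracks / unassigned_detections : indices with no valid pair.
    """

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unassigned_tracks: list[int] = field(default_factory=list)
    unassigned_detections: list[int] = field(default_factory=list)


def build_cost_matrix(track_positions, detection_positions) -> np.ndarray:
    """m x n matrix of Euclidean pixel distances, tracks by detections."""
    tp = np.atleast_2d(np.asarray(track_positions, dtype=float))
    dp = np.atleast_2d(np.asarray(detection_positions, dtype=float))
    if tp.size == 0 or dp.size == 0:
        return np.zeros((len(track_positions), len(detection_positions)))
    diff = tp[:, None, :] - dp[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def solve_lap(C: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-total-cost one-to-one pairing of rows to columns.

    Returns min(m, n) (row, col) pairs whose summed cost is the global
    minimum over all such pairings; surplus rows/columns stay unpaired.  An
    empty matrix yields an empty pairing.  Pairs are reported sorted by row
    index for determinism.
    """
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        return []
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(C)
    return sorted(zip(rows.tolist(), cols.tolist()))


def improved_assignment(
    track_positions,
    detection_positions,
    threshold: float = 60.0,
) -> AssignmentResult:
    """Two-pass gated Hungarian assignment with multiple-to-one resolution.

    Pass 1 solves the global assignment over all tracks x all detections and
    keeps pairs no farther than ``threshold`` (equality is kept).  Pass 2
    re-solves over the tracks left unassigned against *all* detections —
    including already-claimed ones — and gates again.  Where a detection ends
    up claimed by two tracks, only the smaller-distance claim survives and
    the losing track is reported unassigned.

    The threshold is applied *inside* each assignment: over-gate distances
    are replaced by a sentinel cost so they can never bind.  Otherwise a
    surplus detection with no nearby track (a new fruit at the frame edge)
    can divert the global optimum, stealing a track from a detection sitting
    exactly on its predicted trajectory — the mis-assignment the gate exists
    to prevent.  Sentinel pairs are discarded; they report as unassigned.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    m, n = len(track_positions), len(detection_positions)
    result = AssignmentResult()
    if m == 0 or n == 0:
        result.unassigned_tracks = list(range(m))
        result.unassigned_detections = list(range(n))
        return result

    C = build_cost_matrix(track_positions, detection_positions)
    SENTINEL = 1e9  # exceeds any image distance and any gate
    Cg = np.where(C > threshold, SENTINEL, C)

    # pass 1: global optimum over gate-eligible pairs
    claimed: dict[int, tuple[int, float]] = {}  # detection -> (track, distance)
    for ti, dj in solve_lap(Cg):
        d = float(C[ti, dj])
        if d <= threshold:
            claimed[dj] = (ti, d)
    assigned_tracks = {ti for ti, _ in claimed.values()}

    # pass 2: unassigned tracks compete over ALL detections (may create
    # multiple-to-one conflicts), gated identically
    leftovers = [ti for ti in range(m) if ti not in assigned_tracks]
    if leftovers:
        C2 = Cg[leftovers, :]
        for ri, dj in solve_lap(C2):
            ti = leftovers[ri]
            d = float(C[ti, dj])
            if d > threshold:
                continue
            if dj in claimed:
                # multiple-to-one: keep the smaller distance
                if d < claimed[dj][1]:
                    claimed[dj] = (ti, d)
            else:
                claimed[dj] = (ti, d)

    result.pairs = sorted((ti, dj, d) for dj, (ti, d) in claimed.items())
    paired_tracks = {ti for ti, _, _ in result.pairs}
    paired_dets = {dj for _, dj, _ in result.pairs}
    result.unassigned_tracks = [ti for ti in range(m) if ti not in paired_tracks]
    result.unassigned_detections = [dj for dj in range(n) if dj not in paired_dets]
    return result
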