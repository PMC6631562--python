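"""Scoring tracker output against ground truth, and orchard-level statistics.

Two layers:

* a per-video **error taxonomy** — double counts split by cause (temporary
  occlusion, detector false negatives, false position prediction) plus
  missed counts from new fruit being absorbed into an old track's position —
  computable exactly on simulated streams where the ground truth records why
  each detection was absent, and from printed audit counts on real video;

* **orchard comparison statistics** for per-tree counts against a harvest
  tally: bias, RMSE, bias-corrected RMSE (the standard deviation of the
  per-tree errors), percentage of harvest recovered, and the correction
  factor (harvest total / machine-vision total) a grower would apply to
  scale machine counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .io import TrackRecord, STATUS_DETECTED
from .simulate import FALSE_POSITIVE, GroundTruth

__all__ = [
    "ErrorTaxonomy",
    "CountStats",
    "match_tracks_to_truth",
    "error_taxonomy",
    "audit_taxonomy",
    "count_statistics",
    "attach_det_rows",
]


@dataclass(frozen=True)
class ErrorTaxonomy:
    """Video-level count error breakdown.

    Counts are fruit; rates are percentages of the true (seen) count.
    ``estimated_count`` satisfies the identity
    truth_count + total_repeats - missed == estimated_count
    (false-positive-only tracks are reported separately in ``fp_tracks``
    and excluded from the identity).
    """

    truth_count: int
    repeats_occlusion: int
    repeats_fn: int
    repeats_false_prediction: int
    missed_new_assigned_to_old: int
    fp_tracks: int = 0

    @property
    def total_repeats(self) -> int:
        return self.repeats_occlusion + self.repeats_fn + self.repeats_false_prediction

    @property
    def estimated_count(self) -> int:
        return self.truth_count + self.total_repeats - self.missed_new_assigned_to_old

    @property
    def repeat_rate(self) -> float:
        """Double counts as % of true count."""
        return 100.0 * self.total_repeats / self.truth_count

    @property
    def miss_rate(self) -> float:
        """Missed counts as % of true count."""
        return 100.0 * self.missed_new_assigned_to_old / self.truth_count

    @property
    def over_count_rate(self) -> float:
        """Net over-count as % of true count."""
        return self.estimate_ratio - 100.0

    @property
    def estimate_ratio(self) -> float:
        """Estimated count as % of true count."""
        return 100.0 * self.estimated_count / self.truth_count

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            total_repeats=self.total_repeats,
            estimated_count=self.estimated_count,
            repeat_rate=self.repeat_rate,
            miss_rate=self.miss_rate,
            over_count_rate=self.over_count_rate,
            estimate_ratio=self.estimate_ratio,
        )
        return d


def audit_taxonomy(
    truth_count: int,
    repeats_occlusion: int,
    repeats_fn: int,
    repeats_false_prediction: int,
    missed: int,
) -> ErrorTaxonomy:
    """Taxonomy from audit counts (e.g. a human frame-by-frame assessment)."""
    if truth_count <= 0:
        raise ValueError("truth_count must be > 0")
    return ErrorTaxonomy(
        truth_count=truth_count,
        repeats_occlusion=repeats_occlusion,
        repeats_fn=repeats_fn,
        repeats_false_prediction=repeats_false_prediction,
        missed_new_assigned_to_old=missed,
    )


def match_tracks_to_truth(
    records: Sequence[TrackRecord], truth: GroundTruth
) -> dict[int, int]:
    """Map each track id to the fruit providing the majority of its detections.

    Ties break toward the earliest (lowest) fruit id; tracks whose majority
    of detections are hallucinations map to ``FALSE_POSITIVE``.  Records
    must carry detection-row provenance (``det_row``), as produced by an
    in-memory tracking run or :func:`attach_det_rows`.
    """
    votes: dict[int, dict[int, int]] = {}
    for r in records:
        if r.status != STATUS_DETECTED:
            continue
        if r.det_row is None:
            raise ValueError(
                f"record for track {r.track_id} frame {r.frame} lacks det_row provenance"
            )
        fid = truth.provenance[r.frame][r.det_row]
        counts = votes.setdefault(r.track_id, {})
        counts[fid] = counts.get(fid, 0) + 1
    mapping: dict[int, int] = {}
    for tid, counts in votes.items():
        # majority; ties to the earliest real fruit id (FP sorts last)
        best = max(
            counts.items(),
            key=lambda kv: (kv[1], -(kv[0] if kv[0] != FALSE_POSITIVE else np.inf)),
        )
        mapping[tid] = best[0]
    return mapping


def _track_spans(
    records: Sequence[TrackRecord], truth: GroundTruth, fruit: int, track_ids: list[int]
) -> list[tuple[int, int, int]]:
    """(first, last detection frame, track id) of ``fruit``'s detections per track."""
    spans = []
    for tid in track_ids:
        frames = [
            r.frame
            for r in records
            if r.track_id == tid
            and r.status == STATUS_DETECTED
            and truth.provenance[r.frame][r.det_row] == fruit
        ]
        if frames:
            spans.append((min(frames), max(frames), tid))
    return sorted(spans)


def error_taxonomy(
    mapping: Mapping[int, int],
    truth: GroundTruth,
    records: Sequence[TrackRecord],
) -> ErrorTaxonomy:
    """Attribute double counts and misses from a simulated run.

    A fruit claimed by k > 1 tracks contributes k-1 repeats; each repeat
    (the break between two consecutive tracks of the same fruit) is
    attributed by what the ground truth says happened in the gap: an
    occlusion window -> occlusion repeat; a simulated detector miss ->
    false-negative repeat; otherwise the break was a tracking failure
    (false position prediction).  A fruit that emitted detections but owns
    no track — every one of its detections was absorbed by other fruit's
    tracks — is a missed count.
    """
    seen = truth.fruit_seen()
    fruit_tracks: dict[int, list[int]] = {}
    fp_tracks = 0
    for tid, fid in mapping.items():
        if fid == FALSE_POSITIVE:
            fp_tracks += 1
        else:
            fruit_tracks.setdefault(fid, []).append(tid)

    rep_occ = rep_fn = rep_pred = 0
    for fid, tids in fruit_tracks.items():
        if len(tids) < 2:
            continue
        spans = _track_spans(records, truth, fid, tids)
        hist = truth.fruit_frames[fid]
        for (f0, l0, _), (f1, _, _) in zip(spans, spans[1:]):
            gap = range(l0 + 1, f1)
            if any(hist[k].occluded for k in gap if k in hist):
                rep_occ += 1
            elif any(hist[k].fn_dropped for k in gap if k in hist):
                rep_fn += 1
            else:
                rep_pred += 1

    missed = sum(1 for fid in seen if fid not in fruit_tracks)
    return ErrorTaxonomy(
        truth_count=len(seen),
        repeats_occlusion=rep_occ,
        repeats_fn=rep_fn,
        repeats_false_prediction=rep_pred,
        missed_new_assigned_to_old=missed,
        fp_tracks=fp_tracks,
    )


def attach_det_rows(
    records: Sequence[TrackRecord],
    frames: Mapping[int, Sequence],
) -> list[TrackRecord]:
    """Recover detection-row provenance for records loaded from a track CSV.

    Detected records carry the assigned detection's exact box, so a record
    is matched to the detection row in its frame with identical
    (left, top, width, height).
    """
    from dataclasses import replace

    out = []
    for r in records:
        if r.status != STATUS_DETECTED or r.det_row is not None:
            out.append(r)
            continue
        row = None
        for j, d in enumerate(frames.get(r.frame, [])):
            if (d.left, d.top, d.width, d.height) == (r.left, r.top, r.width, r.height):
                row = j
                break
        if row is None:
            raise ValueError(
                f"no detection matches track {r.track_id} box in frame {r.frame}"
            )
        out.append(replace(r, det_row=row))
    return out


@dataclass(frozen=True)
class CountStats:
    """Machine-vision vs reference per-tree count comparison.

    bias is the mean signed per-tree error (MV - reference); rmse_bc is the
    dispersion of per-tree errors after removing that bias, so that
    bias^2 + rmse_bc^2 == rmse^2.  ``pct_of_harvest`` and
    ``correction_factor`` are computed from the totals.
    """

    n_trees: int
    mv_total: float
    harvest_total: float
    per_tree_mean: float
    pct_of_harvest: float
    correction_factor: float
    bias: float | None = None
    rmse: float | None = None
    rmse_bc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def count_statistics(
    per_tree_estimates: Sequence[float] | float,
    per_tree_truth: Sequence[float] | float,
    n_trees: int | None = None,
) -> CountStats:
    """Compare machine-vision per-tree counts against a reference tally.

    Full mode: two equal-length per-tree vectors give bias, RMSE and RMSE-bc
    alongside the total-derived statistics.  Totals-only mode: pass scalar
    totals plus ``n_trees``; only totals-derived quantities (per-tree mean,
    bias, % of harvest, correction factor) are computable, and the
    dispersion statistics are None.
    """
    est_scalar = np.isscalar(per_tree_estimates)
    truth_scalar = np.isscalar(per_tree_truth)
    if est_scalar or truth_scalar:
        if not (est_scalar and truth_scalar):
            raise ValueError("totals-only mode needs scalar estimate and truth totals")
        if n_trees is None or n_trees <= 0:
            raise ValueError("totals-only mode requires n_trees > 0")
        mv_total = float(per_tree_estimates)
        harvest_total = float(per_tree_truth)
        _check_nonneg(mv_total, harvest_total)
        return CountStats(
            n_trees=n_trees,
            mv_total=mv_total,
            harvest_total=harvest_total,
            per_tree_mean=mv_total / n_trees,
            pct_of_harvest=100.0 * mv_total / harvest_total,
            correction_factor=harvest_total / mv_total,
            bias=(mv_total - harvest_total) / n_trees,
        )

    est = np.asarray(per_tree_estimates, dtype=float)
    truth = np.asarray(per_tree_truth, dtype=float)
    if est.shape != truth.shape or est.ndim != 1:
        raise ValueError("per-tree vectors must be 1-D and equal length")
    if n_trees is not None and n_trees != est.size:
        raise ValueError("n_trees disagrees with vector length")
    _check_nonneg(*est, *truth)
    err = est - truth
    bias = float(err.mean())
    rmse = float(np.sqrt((err**2).mean()))
    rmse_bc = float(np.sqrt(((err - bias) ** 2).mean()))
    mv_total, harvest_total = float(est.sum()), float(truth.sum())
    return CountStats(
        n_trees=est.size,
        mv_total=mv_total,
        harvest_total=harvest_total,
        per_tree_mean=mv_total / est.size,
        pct_of_harvest=100.0 * mv_total / harvest_total,
        correction_factor=harvest_total / mv_total,
        bias=bias,
        rmse=rmse,
        rmse_bc=rmse_bc,
    )


def _check_nonneg(*values: float) -> None:
    if any(v < 0 for v in values):
        raise ValueError("counts must be >= 0")
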