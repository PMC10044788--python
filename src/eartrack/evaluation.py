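"""Detection and tracking metrics.

Detection quality is measured by average precision over a precision-recall
curve built with greedy highest-IoU matching at a fixed IoU threshold; the
headline number is the mean AP over thresholds 0.5-0.9 in steps of 0.1
(note: 0.9, not the COCO 0.95, is the top threshold used here).

Tracking quality uses two identity-level tallies per frame against ground
truth:

* ``MOTA = 1 - (FN + FP + IDSW) / GT`` — the CLEAR-MOT accuracy, where GT is
  the total number of identity-frames.  MOTA may be negative.
* ``ICR  = 1 - (Miss + Switch + Drift) / GT`` — the ID correct rate: an
  identity is *missing* when the tracker reports nothing for it, *drifting*
  when it is reported at the wrong position under a consistent identity
  mapping, and *switched* when two or more tracks exchange identities.

For proportion comparisons the "N-1" chi-squared test is provided: the
Pearson statistic on the 2x2 table scaled by (N-1)/N.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from .geometry import BBox, iou
from .io_formats import TrackRecord, ValidationError

__all__ = [
    "ErrorCounts",
    "MatchTable",
    "iou",
    "match_detections",
    "average_precision",
    "map_metric",
    "mota",
    "icr",
    "score_tracks",
    "n1_chisq",
    "MAP_THRESHOLDS",
]

MAP_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class ErrorCounts:
    """Error tallies against ground truth, summed over frames."""

    miss: int = 0
    switch: int = 0
    drift: int = 0
    fn: int = 0
    fp: int = 0
    idsw: int = 0
    gt: int = 0

    def __post_init__(self):
        for name in ("miss", "switch", "drift", "fn", "fp", "idsw"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")


def mota(counts: ErrorCounts) -> float:
    """Multiple Object Tracking Accuracy; <= 1, may be negative."""
    if counts.gt <= 0:
        raise ValidationError("GT must be positive")
    return 1.0 - (counts.fn + counts.fp + counts.idsw) / counts.gt


def icr(counts: ErrorCounts) -> float:
    """ID Correct Rate; <= 1, may be negative."""
    if counts.gt <= 0:
        raise ValidationError("GT must be positive")
    return 1.0 - (counts.miss + counts.switch + counts.drift) / counts.gt


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

@dataclass
class MatchTable:
    """Detections matched to ground truth per IoU threshold.

    ``tp[thr]`` is a boolean array over detections in descending-confidence
    order; ``n_gt`` the total ground-truth count.
    """

    confidences: np.ndarray
    tp: dict[float, np.ndarray] = field(default_factory=dict)
    n_gt: int = 0


def match_detections(gt: list[tuple[int, BBox]],
                     detections: list[tuple[int, BBox, float]],
                     thresholds=MAP_THRESHOLDS) -> MatchTable:
    """Greedy highest-IoU matching per frame at each threshold.

    `gt`: (frame_index, box); `detections`: (frame_index, box, confidence).
    Detections are processed in descending confidence; each may claim at most
    one still-unmatched ground-truth box of the same frame (its highest-IoU
    one, if that IoU reaches the threshold).
    """
    if not gt:
        raise ValidationError("average precision is undefined without ground truth")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i][2], i))
    confs = np.array([detections[i][2] for i in order])
    gt_by_frame: dict[int, list[int]] = {}
    for gi, (fr, _) in enumerate(gt):
        gt_by_frame.setdefault(fr, []).append(gi)
    table = MatchTable(confidences=confs, n_gt=len(gt))
    for thr in thresholds:
        matched = np.zeros(len(gt), bool)
        tp = np.zeros(len(order), bool)
        for rank, di in enumerate(order):
            fr, box, _ = detections[di]
            best, best_iou = -1, 0.0
            for gi in gt_by_frame.get(fr, ()):
                if matched[gi]:
                    continue
                v = iou(box, gt[gi][1])
                if v > best_iou:
                    best, best_iou = gi, v
            if best >= 0 and best_iou >= thr:
                matched[best] = True
                tp[rank] = True
        table.tp[thr] = tp
    return table


def average_precision(table: MatchTable, iou_threshold: float) -> float:
    """All-points interpolated AP at one IoU threshold."""
    tp = table.tp[iou_threshold]
    if len(tp) == 0:
        return 0.0
    tps = np.cumsum(tp)
    fps = np.cumsum(~tp)
    recall = tps / table.n_gt
    precision = tps / (tps + fps)
    # all-points interpolation: envelope of precision from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    return float(np.sum((r[1:] - r[:-1]) * prec_env))


def map_metric(table: MatchTable, thresholds=MAP_THRESHOLDS) -> float:
    """Mean AP over IoU thresholds (default 0.5:0.9 in steps of 0.1)."""
    return float(np.mean([average_precision(table, t) for t in thresholds]))


# ---------------------------------------------------------------------------
# track scoring
# ---------------------------------------------------------------------------

def _per_frame(records: list[TrackRecord]) -> dict[int, dict[int, tuple[float, float]]]:
    out: dict[int, dict[int, tuple[float, float]]] = {}
    for r in records:
        out.setdefault(r.frame_index, {})[r.identity] = (r.x, r.y)
    return out


def score_tracks(pred: list[TrackRecord], truth: list[TrackRecord],
                 match_radius: float, drift_radius: float | None = None,
                 mapping_window: int = 30) -> ErrorCounts:
    """Tally Miss/Switch/Drift (ICR) and FN/FP/IDSW (MOTA) per frame.

    Per frame, predictions are matched one-to-one to ground truth by nearest
    centroid within `match_radius`.  An unmatched truth identity is a miss
    (and FN); a matched one is a switch when the matched prediction identity
    disagrees with the majority mapping over the preceding `mapping_window`
    frames, a drift when the identity is consistent but the position error
    exceeds `drift_radius` (default `match_radius / 2`), and correct
    otherwise.  IDSW follows CLEAR semantics (change against the last
    matched prediction identity).  GT is frames x declared identities.
    """
    if drift_radius is None:
        drift_radius = match_radius / 2.0
    truth_pf = _per_frame(truth)
    pred_pf = _per_frame(pred)
    if not truth_pf:
        raise ValidationError("empty ground truth")
    frames = sorted(truth_pf)
    ids = sorted(truth_pf[frames[0]])
    for t in frames:
        if sorted(truth_pf[t]) != ids:
            raise ValidationError(
                f"ground-truth identity set changes at frame {t}")
    counts = ErrorCounts(gt=len(frames) * len(ids))
    votes: deque[tuple[int, int, int]] = deque()  # (frame, truth_id, pred_id)
    last_match: dict[int, int] = {}
    for t in frames:
        tr = truth_pf[t]
        pr = pred_pf.get(t, {})
        t_ids = list(tr)
        p_ids = list(pr)
        pairs: dict[int, tuple[int, float]] = {}  # truth_id -> (pred_id, dist)
        if p_ids:
            dist = np.full((len(t_ids), len(p_ids)), np.inf)
            for i, ti in enumerate(t_ids):
                for j, pj in enumerate(p_ids):
                    d = float(np.hypot(tr[ti][0] - pr[pj][0],
                                       tr[ti][1] - pr[pj][1]))
                    if d <= match_radius:
                        dist[i, j] = d
            big = match_radius * 1e6 + 1.0
            cost = np.where(np.isinf(dist), big, dist)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if np.isfinite(dist[i, j]):
                    pairs[t_ids[i]] = (p_ids[j], dist[i, j])
        # expected mapping: majority vote over the preceding window
        while votes and votes[0][0] < t - mapping_window:
            votes.popleft()
        expected: dict[int, int] = {}
        tally: dict[int, dict[int, list]] = {}
        for vf, vt, vp in votes:
            tally.setdefault(vt, {}).setdefault(vp, [0, 0])
            tally[vt][vp][0] += 1
            tally[vt][vp][1] = vf
        for vt, opts in tally.items():
            expected[vt] = max(opts.items(), key=lambda kv: (kv[1][0], kv[1][1]))[0]
        matched_pred = set()
        for ti in t_ids:
            if ti not in pairs:
                counts.miss += 1
                counts.fn += 1
                continue
            pj, d = pairs[ti]
            matched_pred.add(pj)
            if ti in last_match and last_match[ti] != pj:
                counts.idsw += 1
            last_match[ti] = pj
            if ti in expected and expected[ti] != pj:
                counts.switch += 1
            elif d > drift_radius:
                counts.drift += 1
            votes.append((t, ti, pj))
        counts.fp += len(p_ids) - len(matched_pred)
    return counts


# ---------------------------------------------------------------------------
# proportion comparison
# ---------------------------------------------------------------------------

def n1_chisq(successes_a: int, n_a: int, successes_b: int, n_b: int) -> float:
    """Two-sided p of the "N-1" chi-squared test on two proportions.

    The Pearson chi-squared statistic of the 2x2 table is multiplied by
    (N-1)/N with N = n_a + n_b; p comes from the chi-squared distribution
    with one degree of freedom.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValidationError("sample sizes must be positive")
    if not (0 <= successes_a <= n_a and 0 <= successes_b <= n_b):
        raise ValidationError("successes must lie in [0, n]")
    a, b = successes_a, n_a - successes_a
    c, d = successes_b, n_b - successes_b
    n = n_a + n_b
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        raise ValidationError("degenerate 2x2 table (zero margin)")
    stat = n * (a * d - b * c) ** 2 / (n_a * n_b * col1 * col2)
    stat *= (n - 1) / n
    return float(chi2.sf(stat, df=1))
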