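"""Metric arithmetic, oracle equivalences and track-scoring semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eartrack.evaluation import (ErrorCounts, average_precision, icr,
                                 map_metric, match_detections, mota, n1_chisq,
                                 score_tracks)
from eartrack.geometry import BBox, iou
from eartrack.io_formats import TrackRecord, ValidationError


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def test_iou_examples():
    a = BBox(0, 0, 2, 2)
    assert iou(a, a) == 1.0
    assert iou(a, BBox(5, 5, 7, 7)) == 0.0
    # inter = 1, union = 4 + 4 - 1 = 7
    assert np.isclose(iou(a, BBox(1, 1, 3, 3)), 1 / 7)


def test_degenerate_box_rejected():
    with pytest.raises(ValueError):
        BBox(0, 0, 0, 2)


@settings(derandomize=True, max_examples=100)
@given(st.tuples(*[st.floats(-50, 50) for _ in range(4)]),
       st.tuples(*[st.floats(-50, 50) for _ in range(4)]))
def test_iou_symmetric_and_bounded(ta, tb):
    def mk(t):
        x0, y0, w, h = t
        return BBox(x0, y0, x0 + abs(w) + 0.1, y0 + abs(h) + 0.1)
    a, b = mk(ta), mk(tb)
    v = iou(a, b)
    assert 0.0 <= v <= 1.0 + 1e-12
    assert np.isclose(v, iou(b, a))


# ---------------------------------------------------------------------------
# ICR / MOTA arithmetic
# ---------------------------------------------------------------------------

def test_icr_published_two_subject_benchmarks():
    # two-mouse benchmark videos: GT = frames x 2 identities
    cases = [
        ((0, 0, 135, 2 * 16000), 0.9958),       # top tracker, video 1
        ((8730, 1796, 0, 2 * 16000), 0.6711),   # detection-poor tracker
    ]
    for (miss, switch, drift, gt), expected in cases:
        counts = ErrorCounts(miss=miss, switch=switch, drift=drift, gt=gt)
        assert round(icr(counts), 4) == expected


def test_mota_values_and_negativity():
    assert mota(ErrorCounts(fn=0, fp=0, idsw=0, gt=100)) == 1.0
    assert np.isclose(mota(ErrorCounts(fn=10, fp=5, idsw=5, gt=100)), 0.80)
    assert np.isclose(mota(ErrorCounts(fn=60, fp=60, idsw=0, gt=100)), -0.20)
    with pytest.raises(ValidationError):
        mota(ErrorCounts(gt=0))
    with pytest.raises(ValidationError):
        icr(ErrorCounts(gt=0))


def test_icr_mota_decrease_in_each_error():
    base = ErrorCounts(miss=1, switch=1, drift=1, fn=1, fp=1, idsw=1, gt=100)
    for name in ("miss", "switch", "drift"):
        worse = ErrorCounts(**{**base.__dict__, name: 2})
        assert icr(worse) < icr(base)
    for name in ("fn", "fp", "idsw"):
        worse = ErrorCounts(**{**base.__dict__, name: 2})
        assert mota(worse) < mota(base)


# ---------------------------------------------------------------------------
# average precision vs brute-force PR oracle
# ---------------------------------------------------------------------------

def oracle_ap(gt, dets, thr):
    """Independent AP: for each confidence prefix recompute matches from
    scratch with explicit loops, then integrate the all-points envelope
    directly from its definition."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][2], i))
    points = []
    for k in range(1, len(order) + 1):
        used = set()
        tp = 0
        for di in order[:k]:
            fr, box, _ = dets[di]
            cand = [(iou(box, g[1]), gi) for gi, g in enumerate(gt)
                    if g[0] == fr and gi not in used]
            cand = [c for c in cand if c[0] >= thr]
            if cand:
                best = max(cand, key=lambda c: c[0])
                used.add(best[1])
                tp += 1
        points.append((tp / len(gt), tp / k))
    ap = 0.0
    recalls = sorted({r for r, _ in points})
    prev_r = 0.0
    for r in recalls:
        p_interp = max((p for rr, p in points if rr >= r), default=0.0)
        ap += (r - prev_r) * p_interp
        prev_r = r
    return ap


def test_ap_single_perfect_detection():
    gt = [(0, BBox(0, 0, 10, 10))]
    dets = [(0, BBox(0, 0, 10, 9), 0.9)]  # IoU 0.9
    table = match_detections(gt, dets)
    assert average_precision(table, 0.5) == 1.0


def test_map_is_mean_of_levels():
    # one GT; detection IoU ~0.72 -> AP 1 at thresholds .5,.6,.7 and 0 above
    gt = [(0, BBox(0, 0, 10, 10))]
    dets = [(0, BBox(0, 0, 10, 7.2), 0.9)]
    table = match_detections(gt, dets)
    aps = [average_precision(table, t) for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
    assert aps == [1.0, 1.0, 1.0, 0.0, 0.0]
    assert np.isclose(map_metric(table), 0.6)


def test_empty_ground_truth_is_an_error():
    with pytest.raises(ValidationError):
        match_detections([], [(0, BBox(0, 0, 1, 1), 0.5)])


@pytest.mark.parametrize("seed", range(40))
def test_ap_equals_bruteforce_oracle_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    n_gt = rng.integers(1, 5)
    n_det = rng.integers(0, 7)

    def rand_box():
        x0, y0 = rng.uniform(0, 20, 2)
        w, h = rng.uniform(2, 10, 2)
        return BBox(x0, y0, x0 + w, y0 + h)

    gt = [(int(rng.integers(0, 2)), rand_box()) for _ in range(n_gt)]
    dets = [(int(rng.integers(0, 2)), rand_box(), float(rng.random()))
            for _ in range(n_det)]
    table = match_detections(gt, dets)
    for thr in (0.3, 0.5, 0.7):
        table2 = match_detections(gt, dets, thresholds=(thr,))
        assert np.isclose(average_precision(table2, thr),
                          oracle_ap(gt, dets, thr), atol=1e-12)


# ---------------------------------------------------------------------------
# score_tracks
# ---------------------------------------------------------------------------

def straight_tracks(n_frames=60, ids=(1, 2), gap=50.0):
    recs = []
    for t in range(n_frames):
        for k, ident in enumerate(ids):
            recs.append(TrackRecord(t, ident, 10.0 + t, 10.0 + k * gap))
    return recs


def test_score_tracks_identity_on_itself():
    truth = straight_tracks()
    counts = score_tracks(truth, truth, match_radius=10.0, drift_radius=5.0)
    assert (counts.miss, counts.switch, counts.drift) == (0, 0, 0)
    assert (counts.fn, counts.fp, counts.idsw) == (0, 0, 0)
    assert icr(counts) == 1.0


def test_score_tracks_counts_swap_as_switches():
    truth = straight_tracks(n_frames=40)
    pred = []
    for r in truth:
        ident = r.identity
        if r.frame_index >= 20:  # identities exchanged from frame 20 on
            ident = 3 - ident
        pred.append(TrackRecord(r.frame_index, ident, r.x, r.y))
    counts = score_tracks(pred, truth, match_radius=10.0, drift_radius=5.0,
                          mapping_window=30)
    # both identities wrong on frames 20..34 under the frozen prior mapping,
    # until the majority vote over the preceding 31-frame window flips
    assert counts.switch == 2 * 15
    assert counts.miss == 0 and counts.drift == 0
    assert counts.idsw == 2  # one exchange, two tracks


def test_score_tracks_deleted_identity_is_missed():
    truth = straight_tracks(n_frames=30)
    pred = [r for r in truth if not (r.identity == 2 and 10 <= r.frame_index < 18)]
    counts = score_tracks(pred, truth, match_radius=10.0, drift_radius=5.0)
    assert counts.miss == 8 and counts.fn == 8
    assert counts.switch == 0 and counts.fp == 0


def test_score_tracks_drift_radius():
    truth = straight_tracks(n_frames=30)
    pred = [TrackRecord(r.frame_index, r.identity, r.x + (7 if r.identity == 1 else 0), r.y)
            for r in truth]
    counts = score_tracks(pred, truth, match_radius=20.0, drift_radius=5.0)
    assert counts.drift == 30 and counts.switch == 0 and counts.miss == 0


def test_score_tracks_requires_consistent_identities():
    truth = straight_tracks(n_frames=5) + [TrackRecord(5, 1, 0, 0)]
    with pytest.raises(ValidationError):
        score_tracks(truth, truth, match_radius=10)


@pytest.mark.parametrize("perm_seed", range(5))
def test_icr_invariant_to_frame_permutation(perm_seed):
    """Tallies are per-frame sums, so shuffling record order changes nothing."""
    truth = straight_tracks(n_frames=25)
    rng = np.random.default_rng(perm_seed)
    pred = [r for r in truth if rng.random() > 0.1]
    missing = {(r.frame_index, r.identity) for r in truth} - \
              {(r.frame_index, r.identity) for r in pred}
    counts = score_tracks(pred, truth, match_radius=10, drift_radius=5)
    assert counts.miss == len(missing)
    shuffled = list(pred)
    rng.shuffle(shuffled)
    counts2 = score_tracks(shuffled, truth, match_radius=10, drift_radius=5)
    assert counts2.__dict__ == counts.__dict__


# ---------------------------------------------------------------------------
# "N-1" chi-squared
# ---------------------------------------------------------------------------

def test_n1_chisq_identical_proportions():
    assert np.isclose(n1_chisq(50, 100, 50, 100), 1.0, atol=1e-9)


def test_n1_chisq_strong_difference():
    # Pearson chi2 = 24.0 on (90/100 vs 60/100); x 199/200 = 23.88
    p = n1_chisq(90, 100, 60, 100)
    assert p < 0.001


def test_n1_chisq_matches_hand_computation():
    from scipy.stats import chi2 as chi2_dist
    a, na, b, nb = 30, 50, 18, 60
    obs = np.array([[a, na - a], [b, nb - b]])
    n = obs.sum()
    row = obs.sum(1, keepdims=True)
    col = obs.sum(0, keepdims=True)
    exp = row * col / n
    pearson = ((obs - exp) ** 2 / exp).sum()
    expected_p = chi2_dist.sf(pearson * (n - 1) / n, 1)
    assert np.isclose(n1_chisq(a, na, b, nb), expected_p, rtol=1e-12)


def test_n1_chisq_zero_margin_rejected():
    with pytest.raises(ValidationError):
        n1_chisq(0, 10, 0, 10)
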