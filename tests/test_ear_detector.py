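"""Ear detector: focus transform, architecture contracts, NMS oracle,
training determinism and scaled-down detection quality."""

import numpy as np
import pytest

from eartrack import nn
from eartrack.ear_detector import (BASELINE_STRIDES, Detection, DetectorConfig,
                                   build_network, count_parameters, detect_ears,
                                   evaluate_map, fit_anchors, focus_inverse,
                                   focus_transform, load_model, nms,
                                   route_stride, save_model, train_detector)
from eartrack.geometry import BBox, iou
from eartrack.io_formats import LabelRecord, ValidationError
from eartrack.synthetic_arena import ArenaSpec, make_video

rng = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# focus transform
# ---------------------------------------------------------------------------

class TestFocus:
    def test_shape_contract(self):
        out = focus_transform(np.zeros((4, 4, 1)))
        assert out.shape == (2, 2, 4)

    def test_lossless_roundtrip(self):
        img = rng.integers(0, 255, (8, 6, 3)).astype(float)
        assert np.array_equal(focus_inverse(focus_transform(img)), img)

    def test_constant_image(self):
        out = focus_transform(np.full((6, 6), 7.0))
        assert (out == 7.0).all()

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValidationError):
            focus_transform(np.zeros((5, 4)))


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def tiny_cfg(**kw):
    base = dict(width=2, epochs=2, batch_size=4, seed=0)
    base.update(kw)
    return DetectorConfig(**base)


class TestArchitecture:
    def test_baseline_grid_shapes(self):
        model = build_network(tiny_cfg(improved=False))
        model.anchors = {s: [(6.0, 6.0)] for s in model.config.strides}
        out = model(nn.Tensor(rng.random((1, 1, 160, 160)).astype(np.float32)))
        assert sorted(out) == [8, 16, 32]
        for s, (box, obj) in out.items():
            assert box.data.shape == (1, 4, 160 // s, 160 // s)
            assert obj.data.shape == (1, 1, 160 // s, 160 // s)

    def test_improved_adds_stride4_grid(self):
        model = build_network(tiny_cfg(improved=True))
        out = model(nn.Tensor(rng.random((1, 1, 160, 160)).astype(np.float32)))
        assert sorted(out) == [4, 8, 16, 32]
        assert out[4][0].data.shape == (1, 4, 40, 40)

    def test_improved_has_strictly_more_parameters(self):
        base = count_parameters(build_network(tiny_cfg(improved=False)))
        improved = count_parameters(build_network(tiny_cfg(improved=True)))
        assert improved > base

    def test_incompatible_input_size_rejected(self):
        model = build_network(tiny_cfg())
        with pytest.raises(ValidationError):
            model(nn.Tensor(rng.random((1, 1, 100, 100))))


def test_route_stride_prefers_matching_scale():
    strides = (4, 8, 16, 32)
    assert route_stride(BBox(0, 0, 6, 6), strides) == 4
    assert route_stride(BBox(0, 0, 24, 24), strides) == 16
    assert route_stride(BBox(0, 0, 6, 6), BASELINE_STRIDES) == 8


def test_fit_anchors_matches_routed_means():
    labels = [LabelRecord(0, 0, BBox(0, 0, 6, 6)),
              LabelRecord(0, 0, BBox(10, 10, 17, 17))]
    anchors = fit_anchors(labels, (4, 8, 16, 32))
    assert np.allclose(anchors[4][0], (6.5, 6.5))  # both route to stride 4


# ---------------------------------------------------------------------------
# NMS vs exhaustive oracle
# ---------------------------------------------------------------------------

def oracle_nms(dets, thr):
    """Independent re-simulation with explicit set logic."""
    remaining = sorted(range(len(dets)),
                       key=lambda i: (-dets[i].confidence, i))
    kept = []
    while remaining:
        i = remaining.pop(0)
        kept.append(i)
        remaining = [j for j in remaining
                     if iou(dets[i].box, dets[j].box) < thr]
    return [dets[i] for i in kept]


class TestNMS:
    def test_identical_boxes_keep_highest(self):
        b = BBox(0, 0, 4, 4)
        out = nms([Detection(b, 0.9), Detection(b, 0.8)], 0.5)
        assert len(out) == 1 and out[0].confidence == 0.9

    def test_disjoint_boxes_kept(self):
        out = nms([Detection(BBox(0, 0, 2, 2), 0.9),
                   Detection(BBox(10, 10, 12, 12), 0.8)], 0.5)
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle_up_to_8_boxes(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(0, 9))
        dets = []
        for _ in range(n):
            x0, y0 = r.uniform(0, 20, 2)
            w, h = r.uniform(1, 8, 2)
            dets.append(Detection(BBox(x0, y0, x0 + w, y0 + h),
                                  float(r.random())))
        for thr in (0.2, 0.5, 0.8):
            assert nms(dets, thr) == oracle_nms(dets, thr)

    def test_bad_threshold(self):
        with pytest.raises(ValidationError):
            nms([], 0.0)


# ---------------------------------------------------------------------------
# training (scaled down)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def detector_training_data():
    """Diverse single-subject frames sampled by striding a longer clip."""
    spec = ArenaSpec(width=96, height=96, n_subjects=1, body_axes=(11.0, 5.5),
                     ear_radius=3.0, speed_scale=3.0, n_frames=320,
                     noise_sd=2.0, seed=3)
    seq, truth = make_video(spec)
    labels = {}
    for r in truth.label_records():
        labels.setdefault(r.frame_index, []).append(r)

    def subset(idx):
        frames = [seq.frames[i] for i in idx]
        recs = [LabelRecord(k, r.class_id, r.box, r.identity)
                for k, i in enumerate(idx) for r in labels[i]]
        return frames, recs

    train = subset(range(0, 320, 8))
    test = subset(range(4, 320, 16))
    return spec, train, test


@pytest.fixture(scope="session")
def trained_detector(detector_training_data):
    """One well-trained improved detector shared across the suite."""
    _, (train_f, train_l), _ = detector_training_data
    cfg = DetectorConfig(improved=True, width=8, epochs=120, batch_size=8,
                         learning_rate=0.02, seed=0)
    model = build_network(cfg)
    losses = train_detector(model, train_f, train_l, cfg)
    return model, losses


class TestTraining:
    def test_loss_decreases(self, trained_detector):
        _, losses = trained_detector
        assert losses[-1] < losses[0]

    def test_determinism_same_seed(self, detector_training_data):
        _, (train_f, train_l), _ = detector_training_data
        logs = []
        for _ in range(2):
            cfg = DetectorConfig(improved=False, width=4, epochs=3,
                                 batch_size=8, learning_rate=0.02, seed=7)
            model = build_network(cfg)
            logs.append(train_detector(model, train_f[:8],
                                       [r for r in train_l if r.frame_index < 8],
                                       cfg))
        assert logs[0] == logs[1]

    def test_unmatchable_labels_rejected(self, detector_training_data):
        _, (train_f, _), _ = detector_training_data
        cfg = DetectorConfig(improved=False, width=4, epochs=1, seed=0)
        model = build_network(cfg)
        # anchor wildly different from every label size -> no positives
        model.anchors = {s: [(60.0, 1.0)] for s in cfg.strides}
        bad = [LabelRecord(0, 0, BBox(10, 10, 16, 16))]
        with pytest.raises(ValidationError):
            train_detector(model, train_f[:1], bad, cfg)


class TestDetection:
    def test_held_out_map_at_05(self, trained_detector, detector_training_data):
        """Scaled-down quality bar: mAP@0.5 >= 0.80 on a held-out split."""
        model, _ = trained_detector
        _, _, (test_f, test_l) = detector_training_data
        assert evaluate_map(model, test_f, test_l, thresholds=(0.5,)) >= 0.80

    def test_blank_frame_yields_nothing(self, trained_detector,
                                        detector_training_data):
        model, _ = trained_detector
        spec = detector_training_data[0]
        blank = np.full((96, 96), spec.background_intensity, dtype=np.uint8)
        assert detect_ears(model, blank, confidence_threshold=0.5) == []

    def test_threshold_one_yields_nothing(self, trained_detector,
                                          detector_training_data):
        model, _ = trained_detector
        _, _, (test_f, _) = detector_training_data
        assert detect_ears(model, test_f[0], confidence_threshold=1.0) == []

    def test_boxes_clipped_to_frame(self, trained_detector,
                                    detector_training_data):
        model, _ = trained_detector
        _, _, (test_f, _) = detector_training_data
        for frame in test_f[:5]:
            for d in detect_ears(model, frame, confidence_threshold=0.1):
                assert 0 <= d.box.x_min < d.box.x_max <= 96
                assert 0 <= d.box.y_min < d.box.y_max <= 96

    def test_two_subject_recall(self, trained_detector):
        """Each ground-truth ear of a 2-subject scene is found at IoU >= 0.5."""
        model, _ = trained_detector
        spec = ArenaSpec(width=96, height=96, n_subjects=2,
                         body_axes=(11.0, 5.5), ear_radius=3.0,
                         speed_scale=2.5, n_frames=40, noise_sd=2.0, seed=19)
        seq, truth = make_video(spec)
        # score frames without occlusion only: ears can hide under a crossing
        hits = total = 0
        for t in range(0, 40, 4):
            if truth.occluded[t].any():
                continue
            dets = detect_ears(model, seq.frames[t], confidence_threshold=0.25)
            for s in range(2):
                for box in truth.ear_boxes[t][s]:
                    total += 1
                    if any(iou(box, d.box) >= 0.5 for d in dets):
                        hits += 1
        assert total > 0
        assert hits / total >= 0.8

    def test_model_roundtrip(self, trained_detector, detector_training_data,
                             tmp_path):
        model, _ = trained_detector
        _, _, (test_f, _) = detector_training_data
        p = tmp_path / "det.npz"
        save_model(model, p)
        back = load_model(p)
        d1 = detect_ears(model, test_f[0])
        d2 = detect_ears(back, test_f[0])
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert np.allclose(a.box.as_array(), b.box.as_array())
            assert a.confidence == b.confidence
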