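"""Pair construction, contrastive loss, dual-Siamese training and assignment."""

import itertools

import numpy as np
import pytest

from eartrack.geometry import BBox
from eartrack.io_formats import ValidationError
from eartrack.preprocess import auto_label_ears, label_ear_identities
from eartrack.siamese_id import (EarObservation, PairSample, SiameseConfig,
                                 SimilarityModel, assign_identities,
                                 contrastive_loss, extract_observation,
                                 group_ears_to_individuals,
                                 load_similarity_model, make_pairs,
                                 pair_similarity, save_similarity_model,
                                 solve_assignment, train_similarity)
from eartrack.synthetic_arena import ArenaSpec, make_video


def dummy_obs(frame_index, identity=1, xy=(10.0, 10.0), value=0.5):
    return EarObservation(frame_index=frame_index,
                          box=BBox(xy[0] - 2, xy[1] - 2, xy[0] + 2, xy[1] + 2),
                          crop=np.full((8, 8), value, dtype=np.float32),
                          centroid=xy, norm_xy=(xy[0] / 100, xy[1] / 100),
                          identity=identity)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

class TestMakePairs:
    def test_adjacency_bounds_positive_count(self):
        obs = ([dummy_obs(t, identity=1) for t in range(5)]
               + [dummy_obs(t + 100, identity=1) for t in range(3)])
        with pytest.raises(ValidationError, match="6"):
            make_pairs(obs, frame_rate=20, neg_gap_seconds=0.1,
                       n_pos=7, n_neg=1)
        pairs = make_pairs(obs, frame_rate=20, neg_gap_seconds=0.1,
                           n_pos=6, n_neg=5, seed=0)
        assert sum(p.label for p in pairs) == 6

    def test_negative_gap_rule(self):
        # 20 fps with a 60 s gap: negatives must be > 1200 frames apart
        obs = [dummy_obs(t, identity=1) for t in range(1400)]
        pairs = make_pairs(obs, frame_rate=20, neg_gap_seconds=60,
                           n_pos=10, n_neg=20, seed=1)
        for p in pairs:
            if p.label == 0:
                assert abs(p.obs_b.frame_index - p.obs_a.frame_index) > 1200
            else:
                assert abs(p.obs_b.frame_index - p.obs_a.frame_index) == 1

    def test_determinism(self):
        obs = [dummy_obs(t, identity=i) for t in range(40) for i in (1, 2)]
        a = make_pairs(obs, 20, 0.5, n_pos=20, n_neg=20, seed=5)
        b = make_pairs(obs, 20, 0.5, n_pos=20, n_neg=20, seed=5)
        assert a == b


# ---------------------------------------------------------------------------
# contrastive loss
# ---------------------------------------------------------------------------

class TestContrastive:
    @pytest.mark.parametrize("d,y,m,expected", [
        (0.0, 1, 1.0, 0.0),
        (1.0, 0, 1.0, 0.0),       # at the margin: no penalty
        (0.5, 0, 1.0, 0.25),
        (0.3, 1, 1.0, 0.09),
        (2.0, 0, 1.0, 0.0),       # beyond the margin
    ])
    def test_closed_form(self, d, y, m, expected):
        assert contrastive_loss(d, y, m) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            contrastive_loss(-0.1, 1)

    def test_batch_form_matches_scalar(self):
        from eartrack import nn
        d = np.array([0.0, 0.5, 1.3, 0.9])
        y = np.array([1, 0, 0, 1])
        batch = contrastive_loss(nn.Tensor(d), y, 1.0)
        scalar = np.mean([contrastive_loss(float(di), int(yi), 1.0)
                          for di, yi in zip(d, y)])
        assert np.isclose(batch.data, scalar)


# ---------------------------------------------------------------------------
# training (session-scoped; reused by several checks)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def siamese_data():
    spec = ArenaSpec(width=96, height=96, n_subjects=1, body_axes=(11.0, 5.5),
                     ear_radius=3.0, speed_scale=3.0, n_frames=400,
                     noise_sd=2.0, seed=13)
    seq, _ = make_video(spec)
    labels = label_ear_identities(auto_label_ears(seq))
    obs = [extract_observation(seq.frames[r.frame_index], r.box,
                               r.frame_index, crop_size=32,
                               identity=r.identity) for r in labels]
    pairs = make_pairs(obs, frame_rate=40.0, neg_gap_seconds=2.0,
                       n_pos=400, n_neg=400, seed=0)
    return pairs[::2], pairs[1::2]


@pytest.fixture(scope="session")
def trained_siamese(siamese_data):
    train_pairs, _ = siamese_data
    cfg = SiameseConfig(epochs=30, batch_size=64, learning_rate=0.05, seed=0)
    model = SimilarityModel(cfg)
    log = train_similarity(model, train_pairs, cfg)
    return model, log


def heldout_auc(model, pairs):
    scores = np.array([pair_similarity(model, p.obs_a, p.obs_b) for p in pairs])
    ys = np.array([p.label for p in pairs])
    order = np.argsort(scores)
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    n1, n0 = ys.sum(), (1 - ys).sum()
    return (ranks[ys == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestTraining:
    def test_loss_decreases(self, trained_siamese):
        _, log = trained_siamese
        assert log[-1] < log[0]

    def test_heldout_pair_auc(self, trained_siamese, siamese_data):
        model, _ = trained_siamese
        _, test_pairs = siamese_data
        assert heldout_auc(model, test_pairs) >= 0.90

    def test_shuffled_labels_negative_control(self, siamese_data):
        train_pairs, test_pairs = siamese_data
        rng = np.random.default_rng(3)
        labels = rng.permutation([p.label for p in train_pairs])
        shuffled = [PairSample(p.obs_a, p.obs_b, int(y))
                    for p, y in zip(train_pairs, labels)]
        cfg = SiameseConfig(epochs=10, batch_size=64, learning_rate=0.05, seed=0)
        model = SimilarityModel(cfg)
        train_similarity(model, shuffled, cfg)
        assert abs(heldout_auc(model, test_pairs) - 0.5) <= 0.1

    def test_determinism(self, siamese_data):
        train_pairs, _ = siamese_data
        subset = train_pairs[::4]  # both classes present
        logs = []
        for _ in range(2):
            cfg = SiameseConfig(epochs=2, batch_size=64, seed=4)
            model = SimilarityModel(cfg)
            logs.append(train_similarity(model, subset, cfg))
        assert logs[0] == logs[1]

    def test_single_class_rejected(self, siamese_data):
        train_pairs, _ = siamese_data
        pos_only = [p for p in train_pairs if p.label == 1]
        with pytest.raises(ValidationError):
            train_similarity(SimilarityModel(SiameseConfig(epochs=1)), pos_only)

    def test_twin_paths_share_weights(self, trained_siamese):
        """The same branch maps both inputs: identical inputs embed identically."""
        model, _ = trained_siamese
        crop = np.random.default_rng(0).random((1, 1, 32, 32)).astype(np.float32)
        from eartrack import nn
        e1 = model.image_branch(nn.Tensor(crop)).data
        e2 = model.image_branch(nn.Tensor(crop.copy())).data
        assert np.array_equal(e1, e2)


class TestScoring:
    def test_score_bounds_and_symmetry(self, trained_siamese, siamese_data):
        model, _ = trained_siamese
        _, test_pairs = siamese_data
        for p in test_pairs[:20]:
            s_ab = pair_similarity(model, p.obs_a, p.obs_b)
            s_ba = pair_similarity(model, p.obs_b, p.obs_a)
            assert 0.0 <= s_ab <= 1.0
            assert abs(s_ab - s_ba) <= 1e-5

    def test_self_outscores_distant(self, trained_siamese, siamese_data):
        model, _ = trained_siamese
        _, test_pairs = siamese_data
        pos = [p for p in test_pairs if p.label == 1][:10]
        neg = [p for p in test_pairs if p.label == 0][:10]
        for p in pos:
            self_score = pair_similarity(model, p.obs_a, p.obs_a)
            for q in neg:
                assert self_score >= pair_similarity(model, q.obs_a, q.obs_b)

    def test_crop_size_mismatch(self, trained_siamese):
        model, _ = trained_siamese
        a = dummy_obs(0)
        b = EarObservation(1, BBox(0, 0, 4, 4), np.zeros((16, 16),
                                                         dtype=np.float32),
                           (2.0, 2.0), (0.02, 0.02), 1)
        with pytest.raises(ValidationError):
            pair_similarity(model, a, b)


# ---------------------------------------------------------------------------
# assignment solver vs exhaustive oracle
# ---------------------------------------------------------------------------

def oracle_assignment(scores, min_score):
    """Best one-to-one matching by explicit enumeration over permutations."""
    n, m = scores.shape
    best, best_total = {}, -np.inf
    k = min(n, m)
    for rows in itertools.permutations(range(n), k):
        for cols in itertools.permutations(range(m), k):
            total = sum(scores[i, j] for i, j in zip(rows, cols))
            if total > best_total + 1e-12:
                best_total = total
                best = {i: j for i, j in zip(rows, cols)}
    return {i: j for i, j in best.items() if scores[i, j] >= min_score}


class TestAssignment:
    @pytest.mark.parametrize("seed", range(100))
    def test_solver_equals_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 5, size=2)
        scores = rng.random((n, m))
        got = solve_assignment(scores, min_score=0.2)
        want = oracle_assignment(scores, min_score=0.2)
        total_got = sum(scores[i, j] for i, j in got.items())
        total_want = sum(scores[i, j] for i, j in want.items())
        # the solver must achieve the oracle's optimum (ties may differ)
        assert total_got == pytest.approx(total_want, abs=1e-9)

    def test_dominant_diagonal_preserved(self):
        scores = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert solve_assignment(scores, 0.2) == {0: 0, 1: 1}

    def test_all_below_floor_rejected(self):
        scores = np.full((3, 3), 0.05)
        assert solve_assignment(scores, 0.2) == {}

    def test_assign_identities_contract(self, trained_siamese):
        model, _ = trained_siamese
        prev = [dummy_obs(0, identity=5, xy=(10, 10)),
                dummy_obs(0, identity=9, xy=(60, 60))]
        nxt = [dummy_obs(1, identity=None, xy=(61, 60)),
               dummy_obs(1, identity=None, xy=(11, 10))]
        out = assign_identities(model, prev, nxt, min_score=0.0)
        assert {o.identity for o in out} == {5, 9}
        # nearest positions inherit the matching identity
        assert out[0].identity == 9 and out[1].identity == 5
        assert assign_identities(model, prev, [], min_score=0.0) == []


class TestGrouping:
    def test_mean_of_two_ears(self):
        obs = [dummy_obs(0, identity=1, xy=(10, 10)),
               dummy_obs(0, identity=2, xy=(14, 10))]
        pos = group_ears_to_individuals(obs, {1: 1, 2: 1})
        assert pos == {1: (12.0, 10.0)}

    def test_single_visible_ear(self):
        obs = [dummy_obs(0, identity=2, xy=(14, 10))]
        assert group_ears_to_individuals(obs, {1: 1, 2: 1}) == {1: (14.0, 10.0)}

    def test_two_individuals_distinct(self):
        obs = [dummy_obs(0, identity=1, xy=(10, 10)),
               dummy_obs(0, identity=3, xy=(50, 50))]
        pos = group_ears_to_individuals(obs, {1: 1, 2: 1, 3: 2, 4: 2})
        assert set(pos) == {1, 2}

    def test_unknown_ear_rejected(self):
        with pytest.raises(ValidationError):
            group_ears_to_individuals([dummy_obs(0, identity=7)], {1: 1})


def test_model_roundtrip(trained_siamese, siamese_data, tmp_path):
    model, _ = trained_siamese
    _, test_pairs = siamese_data
    p = tmp_path / "sim.npz"
    save_similarity_model(model, p)
    back = load_similarity_model(p)
    for pair in test_pairs[:5]:
        assert pair_similarity(model, pair.obs_a, pair.obs_b) == pytest.approx(
            pair_similarity(back, pair.obs_a, pair.obs_b), abs=1e-6)
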