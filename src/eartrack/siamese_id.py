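"""Dual-Siamese similarity model and identity assignment for occlusion frames.

Two weight-shared (Siamese) branches embed, respectively, the cropped ear
image and its centroid coordinates; each branch is trained with a
contrastive loss on its embedding distance (same ear in adjacent frames
pulled together, temporally distant pairs pushed beyond a margin).  The two
branch distance signals are then concatenated into a small fully connected
fusion head trained with binary cross-entropy, whose sigmoid output is the
pair-similarity score in [0, 1].

Identity assignment between consecutive frames solves a global optimal
one-to-one matching on (1 - score), rejecting matches below a score floor.
Ears are finally grouped into individuals (each individual owns up to two
ear identities, fixed at initialisation from a flanking non-occlusion frame)
whose position is the mean of its visible ear centroids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn
from .geometry import BBox
from .io_formats import ValidationError, get_logger

__all__ = [
    "EarObservation",
    "PairSample",
    "SiameseConfig",
    "SimilarityModel",
    "extract_observation",
    "make_pairs",
    "contrastive_loss",
    "train_similarity",
    "pair_similarity",
    "similarity_matrix",
    "solve_assignment",
    "assign_identities",
    "group_ears_to_individuals",
    "save_similarity_model",
    "load_similarity_model",
]

MODEL_FORMAT_VERSION = 1
DEFAULT_CROP = 32  # px; mouse ears are on the order of 30 x 30 px in HD video


@dataclass(frozen=True)
class EarObservation:
    """A detected ear in one frame: crop, box, centroid and optional identity."""

    frame_index: int
    box: BBox
    crop: np.ndarray            # (crop, crop) float in [0, 1]
    centroid: tuple[float, float]
    norm_xy: tuple[float, float]  # centroid normalised by frame dimensions
    identity: int | None = None

    def __post_init__(self):
        if self.crop.ndim != 2 or self.crop.shape[0] != self.crop.shape[1]:
            raise ValidationError("crop must be a square 2-D array")
        if not (self.box.x_min <= self.centroid[0] <= self.box.x_max
                and self.box.y_min <= self.centroid[1] <= self.box.y_max):
            raise ValidationError("centroid must lie inside the box")


@dataclass(frozen=True)
class PairSample:
    obs_a: EarObservation
    obs_b: EarObservation
    label: int  # 1 = same identity in adjacent frames, 0 = distant context

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError("pair label must be 0 or 1")


def extract_observation(frame: np.ndarray, box: BBox, frame_index: int,
                        crop_size: int = DEFAULT_CROP,
                        identity: int | None = None) -> EarObservation:
    """Build an observation: fixed-size crop centred on the box centre."""
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim == 3:
        f = f.mean(axis=2)
    h, w = f.shape
    cx, cy = box.center
    cx = min(max(cx, 0.0), w - 1.0)
    cy = min(max(cy, 0.0), h - 1.0)
    half = crop_size // 2
    x0, y0 = int(round(cx)) - half, int(round(cy)) - half
    pad = np.pad(f, ((half, half), (half, half)), mode="edge")
    crop = pad[y0 + half:y0 + half + crop_size,
               x0 + half:x0 + half + crop_size] / 255.0
    return EarObservation(frame_index=frame_index, box=box,
                          crop=crop.astype(np.float32),
                          centroid=(float(box.center[0]), float(box.center[1])),
                          norm_xy=(float(box.center[0] / w),
                                   float(box.center[1] / h)),
                          identity=identity)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def make_pairs(observations: list[EarObservation], frame_rate: float,
               neg_gap_seconds: float = 60.0, n_pos: int = 1000,
               n_neg: int = 1000, seed: int = 0) -> list[PairSample]:
    """Sample positive (adjacent same-ear) and negative (distant) pairs.

    Positives pair the same identity in consecutive kept frames; negatives
    pair observations separated by more than ``neg_gap_seconds`` of video.
    Sampling is without replacement, reproducible from the seed.
    """
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be positive")
    if any(o.identity is None for o in observations):
        raise ValidationError("all observations must carry identities")
    gap_frames = neg_gap_seconds * frame_rate
    by_identity: dict[int, list[EarObservation]] = {}
    for o in observations:
        by_identity.setdefault(o.identity, []).append(o)
    positives: list[tuple[EarObservation, EarObservation]] = []
    for obs in by_identity.values():
        obs = sorted(obs, key=lambda o: o.frame_index)
        for a, b in zip(obs, obs[1:]):
            if b.frame_index - a.frame_index == 1:
                positives.append((a, b))
    ordered = sorted(observations, key=lambda o: (o.frame_index, o.identity))
    frames = np.array([o.frame_index for o in ordered])
    negatives: list[tuple[int, int]] = []
    for i in range(len(ordered)):
        j0 = int(np.searchsorted(frames, frames[i] + gap_frames, side="right"))
        negatives.extend((i, j) for j in range(j0, len(ordered)))
    if n_pos > len(positives):
        raise ValidationError(f"requested {n_pos} positive pairs but only "
                              f"{len(positives)} exist")
    if n_neg > len(negatives):
        raise ValidationError(f"requested {n_neg} negative pairs but only "
                              f"{len(negatives)} exist")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 31]))
    pos_idx = rng.choice(len(positives), size=n_pos, replace=False)
    neg_idx = rng.choice(len(negatives), size=n_neg, replace=False)
    pairs = [PairSample(*positives[i], label=1) for i in pos_idx]
    pairs += [PairSample(ordered[negatives[i][0]], ordered[negatives[i][1]],
                         label=0) for i in neg_idx]
    return pairs


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class SiameseConfig:
    crop_size: int = DEFAULT_CROP
    embed_dim: int = 16
    margin: float = 1.0
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 0.05
    final_lr_factor: float = 0.2
    momentum: float = 0.937
    seed: int = 0


class _ImageBranch(nn.Module):
    """Small convolutional embedding applied identically to both crops."""

    def __init__(self, embed_dim, rng):
        self.c1 = nn.ConvBlock(1, 8, kernel=3, stride=2, rng=rng)
        self.c2 = nn.ConvBlock(8, 16, kernel=3, stride=2, rng=rng)
        self.c3 = nn.ConvBlock(16, 16, kernel=3, stride=2, rng=rng)
        self.fc = nn.Linear(16, embed_dim, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc(nn.global_avg_pool(self.c3(self.c2(self.c1(x)))))


class _CoordBranch(nn.Module):
    """Vector embedding of normalised centroids, weight-shared across twins."""

    def __init__(self, embed_dim, rng):
        self.fc1 = nn.Linear(2, 16, rng=rng)
        self.fc2 = nn.Linear(16, embed_dim // 2, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.leaky_relu(self.fc1(x)))


class _FusionHead(nn.Module):
    """Two-layer fully connected head mapping the pair of branch distance
    signals to a similarity logit."""

    def __init__(self, rng):
        self.fc1 = nn.Linear(2, 16, rng=rng)
        self.fc2 = nn.Linear(16, 1, rng=rng)

    def __call__(self, d: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.leaky_relu(self.fc1(d)))


class SimilarityModel(nn.Module):
    """Dual-Siamese pair scorer (image branch + coordinate branch + fusion)."""

    def __init__(self, config: SiameseConfig | None = None):
        self.config = config or SiameseConfig()
        rng = np.random.default_rng(np.random.SeedSequence(
            [self.config.seed & 0x7FFFFFFF, 53]))
        self.image_branch = _ImageBranch(self.config.embed_dim, rng)
        self.coord_branch = _CoordBranch(self.config.embed_dim, rng)
        self.fusion = _FusionHead(rng)

    # -- forward pieces ----------------------------------------------------
    @staticmethod
    def _distance(e1: nn.Tensor, e2: nn.Tensor) -> nn.Tensor:
        return nn.sqrt(((e1 - e2) ** 2).sum(axis=1) + 1e-12)

    def pair_logits(self, crops_a, crops_b, xy_a, xy_b):
        """(N,) similarity logits plus the two branch distances."""
        ea = self.image_branch(nn.Tensor(crops_a))
        eb = self.image_branch(nn.Tensor(crops_b))
        ca = self.coord_branch(nn.Tensor(xy_a))
        cb = self.coord_branch(nn.Tensor(xy_b))
        d_img = self._distance(ea, eb)
        d_coord = self._distance(ca, cb)
        n = d_img.data.shape[0]
        fused = nn.concat([d_img.reshape(n, 1), d_coord.reshape(n, 1)], axis=1)
        return self.fusion(fused).reshape(n), d_img, d_coord


def contrastive_loss(distance, label, margin: float = 1.0):
    """Contrastive loss on an embedding distance.

    Same-class pairs (label 1) pay the squared distance; different-class
    pairs (label 0) pay the squared shortfall below the margin.
    Accepts scalars or (Tensor, array) batches; returns the mean.
    """
    if margin <= 0:
        raise ValidationError("margin must be positive")
    if isinstance(distance, nn.Tensor):
        y = np.asarray(label, dtype=float)
        if (distance.data < 0).any():
            raise ValidationError("distance must be nonnegative")
        pos = distance ** 2
        neg = nn.maximum(margin - distance, 0.0) ** 2
        return (pos * y + neg * (1.0 - y)).mean()
    if distance < 0:
        raise ValidationError("distance must be nonnegative")
    if label == 1:
        return float(distance) ** 2
    return max(0.0, margin - float(distance)) ** 2


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_arrays(pairs: list[PairSample]):
    ca = np.stack([p.obs_a.crop for p in pairs])[:, None]
    cb = np.stack([p.obs_b.crop for p in pairs])[:, None]
    xa = np.array([p.obs_a.norm_xy for p in pairs], dtype=np.float32)
    xb = np.array([p.obs_b.norm_xy for p in pairs], dtype=np.float32)
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return ca, cb, xa, xb, y


def train_similarity(model: SimilarityModel, pairs: list[PairSample],
                     config: SiameseConfig | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean loss log.

    Each branch minimises a contrastive loss on its own embedding distance;
    the fusion head minimises binary cross-entropy on the pair labels.
    Weight sharing between twin paths holds by construction (the same branch
    parameters process both inputs).
    """
    cfg = config or model.config
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValidationError("training pairs must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 59]))
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    steps_per_epoch = max(1, math.ceil(len(pairs) / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    log = get_logger()
    loss_log: list[float] = []
    step = 0
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            batch = [pairs[i] for i in order[b0:b0 + cfg.batch_size]]
            ca, cb, xa, xb, y = _batch_arrays(batch)
            logits, d_img, d_coord = model.pair_logits(ca, cb, xa, xb)
            loss = (contrastive_loss(d_img, y, cfg.margin)
                    + contrastive_loss(d_coord, y, cfg.margin)
                    + nn.bce_with_logits(logits, y))
            opt.zero_grad()
            loss.backward()
            opt.lr = nn.one_cycle_lr(step, total_steps, cfg.learning_rate,
                                     cfg.final_lr_factor)
            opt.step()
            losses.append(float(loss.data))
            step += 1
        loss_log.append(float(np.mean(losses)))
        if epoch % 10 == 0 or epoch == cfg.epochs - 1:
            log.info("siamese epoch %d/%d loss %.4f", epoch + 1, cfg.epochs,
                     loss_log[-1])
    model.eval()
    return loss_log


# ---------------------------------------------------------------------------
# scoring and assignment
# ---------------------------------------------------------------------------

def similarity_matrix(model: SimilarityModel, obs_a: list[EarObservation],
                      obs_b: list[EarObservation]) -> np.ndarray:
    """Pairwise similarity scores, shape (len(a), len(b)), symmetrised."""
    if not obs_a or not obs_b:
        return np.zeros((len(obs_a), len(obs_b)))
    model.eval()
    pairs = [(a, b) for a in obs_a for b in obs_b]
    out = np.empty(len(pairs))
    for orient in range(2):
        first = [p[orient] for p in pairs]
        second = [p[1 - orient] for p in pairs]
        ca = np.stack([o.crop for o in first])[:, None]
        cb = np.stack([o.crop for o in second])[:, None]
        xa = np.array([o.norm_xy for o in first], dtype=np.float32)
        xb = np.array([o.norm_xy for o in second], dtype=np.float32)
        logits, _, _ = model.pair_logits(ca, cb, xa, xb)
        s = 1.0 / (1.0 + np.exp(-logits.data))
        out = s if orient == 0 else (out + s) / 2.0
    return out.reshape(len(obs_a), len(obs_b))


def pair_similarity(model: SimilarityModel, obs_a: EarObservation,
                    obs_b: EarObservation) -> float:
    """Similarity score in [0, 1]; symmetric (both orders averaged)."""
    if obs_a.crop.shape != obs_b.crop.shape:
        raise ValidationError("crop size mismatch between observations")
    return float(similarity_matrix(model, [obs_a], [obs_b])[0, 0])


def solve_assignment(scores: np.ndarray, min_score: float) -> dict[int, int]:
    """Optimal one-to-one matching on a similarity matrix.

    Maximises the total score over all one-to-one matchings (equivalently,
    minimises total 1 - score) and rejects matches below `min_score`.
    Returns {row index -> column index}.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return {}
    rows, cols = linear_sum_assignment(1.0 - scores)
    return {int(i): int(j) for i, j in zip(rows, cols)
            if scores[i, j] >= min_score}


def assign_identities(model: SimilarityModel, prev_obs: list[EarObservation],
                      next_obs: list[EarObservation],
                      min_score: float = 0.2) -> list[EarObservation]:
    """Carry identities from `prev_obs` onto `next_obs`.

    A globally optimal one-to-one matching minimises total (1 - score);
    matches scoring below `min_score` are rejected, leaving those
    observations unassigned (identity None).
    """
    if not prev_obs:
        raise ValidationError("assign_identities requires previous observations")
    if any(o.identity is None for o in prev_obs):
        raise ValidationError("previous observations must carry identities")
    if not next_obs:
        return []
    scores = similarity_matrix(model, prev_obs, next_obs)
    matched = solve_assignment(scores, min_score)
    out = [replace(o, identity=None) for o in next_obs]
    for i, j in matched.items():
        out[j] = replace(next_obs[j], identity=prev_obs[i].identity)
    return out


def group_ears_to_individuals(assigned: list[EarObservation],
                              ear_to_individual: dict[int, int]) -> dict[int, tuple[float, float]]:
    """Individual positions from assigned ears of one frame.

    Each individual owns up to two ear identities (fixed at initialisation
    from the flanking non-occlusion frame); its position is the mean of the
    centroids of its visible ears — one visible ear suffices.
    """
    acc: dict[int, list[tuple[float, float]]] = {}
    for obs in assigned:
        if obs.identity is None:
            continue
        if obs.identity not in ear_to_individual:
            raise ValidationError(
                f"ear identity {obs.identity} is not assigned to any individual")
        acc.setdefault(ear_to_individual[obs.identity], []).append(obs.centroid)
    return {ind: (float(np.mean([c[0] for c in cents])),
                  float(np.mean([c[1] for c in cents])))
            for ind, cents in acc.items()}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_similarity_model(model: SimilarityModel, path: str | Path) -> None:
    from dataclasses import asdict
    meta = json.dumps({"format_version": MODEL_FORMAT_VERSION,
                       "kind": "similarity", "config": asdict(model.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_arrays())


def load_similarity_model(path: str | Path) -> SimilarityModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("kind") != "similarity":
            raise ValidationError(f"{path} is not a similarity model file")
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError("unsupported model format version")
        model = SimilarityModel(SiameseConfig(**meta["config"]))
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__meta__"})
    model.eval()
    return model
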