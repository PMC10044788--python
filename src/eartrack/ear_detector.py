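"""Anchor-based small-object ear detector with a configurable feature pyramid.

The network follows the familiar one-stage layout: a Focus (space-to-depth)
stem, a convolutional backbone with CSP-style residual stages and an SPP
multi-scale max-pool fusion at the deepest level, a PANet-style neck fusing
features top-down and then bottom-up, and 1x1 prediction heads emitting box
offsets and objectness per grid cell.  The baseline pyramid predicts at
strides {8, 16, 32}; the *improved* variant adds a fourth information stream
from the low-level stride-4 backbone layer into the neck, with its own
prediction head, which preserves the fine spatial detail that ears of only a
few pixels need.

Everything runs at desk scale on a CPU: widths are config-scaled (defaults
well under a million parameters), anchors are k-means fit to the training
label sizes, and training is plain SGD with momentum under a one-cycle
cosine schedule.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .geometry import BBox, iou
from .io_formats import LabelRecord, ValidationError, get_logger

__all__ = [
    "Detection",
    "DetectorConfig",
    "focus_transform",
    "focus_inverse",
    "build_network",
    "fit_anchors",
    "nms",
    "train_detector",
    "detect_ears",
    "evaluate_map",
    "save_model",
    "load_model",
    "count_parameters",
]

MODEL_FORMAT_VERSION = 1
_BOX_WEIGHT = 3.0      # box-regression term weight relative to objectness BCE
_OBJ_POS_FRACTION = 0.1  # share of objectness BCE weight carried by positives
_NEG_FLOOR = 0.02        # baseline weight of easy-negative cells
_COORD_WEIGHT = 20.0    # sigmoid-space coordinate regression weight

BASELINE_STRIDES = (8, 16, 32)
IMPROVED_STRIDES = (4, 8, 16, 32)


@dataclass(frozen=True)
class Detection:
    """A detected ear: box (full-frame pixels), confidence, class."""

    box: BBox
    confidence: float
    class_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError("confidence must be in [0, 1]")


@dataclass
class DetectorConfig:
    """Architecture and training settings of the ear detector."""

    improved: bool = True           # add the stride-4 low-level connection
    width: int = 8                  # base channel width of the backbone
    neck_width: int = 0             # 0 = 2 * width
    anchors: dict | None = None     # stride -> [(w, h), ...]; None = k-means fit
    anchor_iou: float = 0.3         # a label is positive where anchor IoU >= this
    confidence_threshold: float = 0.5
    nms_iou: float = 0.45
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 0.01
    final_lr_factor: float = 0.2
    momentum: float = 0.937
    warmup_fraction: float = 0.1    # linear lr ramp over the first steps
    seed: int = 0

    @property
    def strides(self) -> tuple[int, ...]:
        return IMPROVED_STRIDES if self.improved else BASELINE_STRIDES

    def resolved_neck_width(self) -> int:
        return self.neck_width or 2 * self.width

    def __post_init__(self):
        for s in self.strides:
            if s & (s - 1):
                raise ValidationError("strides must be powers of two")
        if self.improved and not set(BASELINE_STRIDES) <= set(self.strides):
            raise ValidationError("improved levels must be a superset of baseline")


# ---------------------------------------------------------------------------
# focus / space-to-depth
# ---------------------------------------------------------------------------

_PHASES = ((0, 0), (1, 0), (0, 1), (1, 1))


def focus_transform(image: np.ndarray) -> np.ndarray:
    """Rearrange an HxWxC image into (H/2)x(W/2)x(4C): the four 2x2 phase
    slices are concatenated along channels.  Lossless."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w, _ = img.shape
    if h % 2 or w % 2:
        raise ValidationError("focus_transform requires even height and width")
    return np.concatenate([img[i::2, j::2, :] for i, j in _PHASES], axis=2)


def focus_inverse(stacked: np.ndarray) -> np.ndarray:
    """Inverse of :func:`focus_transform`."""
    arr = np.asarray(stacked)
    if arr.ndim != 3 or arr.shape[2] % 4:
        raise ValidationError("expected an (H/2)x(W/2)x(4C) array")
    c = arr.shape[2] // 4
    h, w = arr.shape[0] * 2, arr.shape[1] * 2
    out = np.empty((h, w, c), dtype=arr.dtype)
    for k, (i, j) in enumerate(_PHASES):
        out[i::2, j::2, :] = arr[:, :, k * c:(k + 1) * c]
    return out


def _focus_nchw(x: nn.Tensor) -> nn.Tensor:
    """Differentiable focus on an (N,C,H,W) tensor."""
    data = x.data
    c = data.shape[1]
    out = np.concatenate([data[:, :, i::2, j::2] for i, j in _PHASES], axis=1)

    def grad_fn(g):
        gx = np.zeros_like(data)
        for k, (i, j) in enumerate(_PHASES):
            gx[:, :, i::2, j::2] += g[:, k * c:(k + 1) * c]
        return gx

    return nn.Tensor(out, parents=(x,), grad_fns=(grad_fn,))


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class ResUnit(nn.Module):
    def __init__(self, channels, rng):
        self.cbl1 = nn.ConvBlock(channels, channels, kernel=1, rng=rng)
        self.cbl2 = nn.ConvBlock(channels, channels, kernel=3, rng=rng)

    def __call__(self, x):
        return x + self.cbl2(self.cbl1(x))


class CSPBlock(nn.Module):
    """Cross-stage partial block: half the channels through a residual path,
    half through a shortcut projection, concatenated and fused."""

    def __init__(self, channels, rng):
        half = max(channels // 2, 1)
        self.split_a = nn.ConvBlock(channels, half, kernel=1, rng=rng)
        self.split_b = nn.ConvBlock(channels, half, kernel=1, rng=rng)
        self.res = ResUnit(half, rng)
        self.fuse = nn.ConvBlock(2 * half, channels, kernel=1, rng=rng)

    def __call__(self, x):
        return self.fuse(nn.concat([self.res(self.split_a(x)),
                                    self.split_b(x)], axis=1))


class SPP(nn.Module):
    """Spatial pyramid pooling: multi-scale stride-1 max pools, fused 1x1."""

    def __init__(self, channels, rng, kernels=(3, 5)):
        self.kernels = tuple(kernels)
        self.reduce = nn.ConvBlock(channels, channels // 2, kernel=1, rng=rng)
        self.fuse = nn.ConvBlock((channels // 2) * (len(self.kernels) + 1),
                                 channels, kernel=1, rng=rng)

    def __call__(self, x):
        r = self.reduce(x)
        pools = [r] + [nn.maxpool2d_same(r, k) for k in self.kernels]
        return self.fuse(nn.concat(pools, axis=1))


class Backbone(nn.Module):
    """Focus stem + strided CBL/CSP stages; exposes maps at strides 4..32."""

    def __init__(self, width, rng, in_channels=1):
        w = width
        self.stem = nn.ConvBlock(4 * in_channels, w, kernel=3, rng=rng)     # stride 2
        self.down2 = nn.ConvBlock(w, 2 * w, kernel=3, stride=2, rng=rng)    # stride 4
        self.csp2 = CSPBlock(2 * w, rng)
        self.down3 = nn.ConvBlock(2 * w, 4 * w, kernel=3, stride=2, rng=rng)  # 8
        self.csp3 = CSPBlock(4 * w, rng)
        self.down4 = nn.ConvBlock(4 * w, 6 * w, kernel=3, stride=2, rng=rng)  # 16
        self.csp4 = CSPBlock(6 * w, rng)
        self.down5 = nn.ConvBlock(6 * w, 8 * w, kernel=3, stride=2, rng=rng)  # 32
        self.spp = SPP(8 * w, rng)
        self.channels = {4: 2 * w, 8: 4 * w, 16: 6 * w, 32: 8 * w}

    def __call__(self, x):
        x = self.stem(_focus_nchw(x))
        c2 = self.csp2(self.down2(x))
        c3 = self.csp3(self.down3(c2))
        c4 = self.csp4(self.down4(c3))
        c5 = self.spp(self.down5(c4))
        return {4: c2, 8: c3, 16: c4, 32: c5}


class PANeck(nn.Module):
    """Top-down then bottom-up fusion over the configured pyramid levels."""

    def __init__(self, backbone_channels, strides, neck_width, rng):
        self.strides = tuple(sorted(strides))
        nc = neck_width
        self.lateral = [nn.ConvBlock(backbone_channels[s], nc, kernel=1, rng=rng)
                        for s in self.strides]
        self.td = [nn.ConvBlock(2 * nc, nc, kernel=3, rng=rng)
                   for _ in self.strides[:-1]]
        self.down = [nn.ConvBlock(nc, nc, kernel=3, stride=2, rng=rng)
                     for _ in self.strides[:-1]]
        self.bu = [nn.ConvBlock(2 * nc, nc, kernel=3, rng=rng)
                   for _ in self.strides[:-1]]

    def __call__(self, feats):
        lat = [l(feats[s]) for l, s in zip(self.lateral, self.strides)]
        # top-down: coarsest to finest
        p = [None] * len(lat)
        p[-1] = lat[-1]
        for i in range(len(lat) - 2, -1, -1):
            p[i] = self.td[i](nn.concat([nn.upsample2x(p[i + 1]), lat[i]], axis=1))
        # bottom-up: finest to coarsest
        out = [None] * len(lat)
        out[0] = p[0]
        for i in range(1, len(lat)):
            out[i] = self.bu[i - 1](nn.concat([self.down[i - 1](out[i - 1]),
                                               p[i]], axis=1))
        return dict(zip(self.strides, out))


class EarDetector(nn.Module):
    """Backbone + neck + per-level box/objectness heads."""

    def __init__(self, config: DetectorConfig):
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed & 0x7FFFFFFF, 101]))
        self.config = config
        self.backbone = Backbone(config.width, rng)
        nc = config.resolved_neck_width()
        self.neck = PANeck(self.backbone.channels, config.strides, nc, rng)
        na = 1  # one anchor per level
        self.box_heads = [nn.Conv2d(nc, 4 * na, kernel=1, rng=rng)
                          for _ in config.strides]
        self.obj_heads = [nn.Conv2d(nc, na, kernel=1, rng=rng)
                          for _ in config.strides]
        self.anchors = config.anchors or {}

    def __call__(self, x: nn.Tensor):
        h, w = x.data.shape[2], x.data.shape[3]
        smax = max(self.config.strides)
        if h % smax or w % smax or h < smax or w < smax:
            raise ValidationError(
                f"input {h}x{w} cannot produce pyramid levels {self.config.strides}")
        feats = self.neck(self.backbone(x))
        return {s: (self.box_heads[i](feats[s]), self.obj_heads[i](feats[s]))
                for i, s in enumerate(self.config.strides)}


def build_network(config: DetectorConfig) -> EarDetector:
    """Instantiate the detector; weights seeded from the config."""
    return EarDetector(config)


def count_parameters(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# anchors and target assignment
# ---------------------------------------------------------------------------

def _wh_iou(wh_a, wh_b) -> float:
    """IoU of two boxes of given sizes, both anchored at the origin."""
    inter = min(wh_a[0], wh_b[0]) * min(wh_a[1], wh_b[1])
    return inter / (wh_a[0] * wh_a[1] + wh_b[0] * wh_b[1] - inter)


_CANONICAL_RATIO = 1.5  # preferred object size in grid cells at its level


def route_stride(box: BBox, strides) -> int:
    """The pyramid level whose cell size best matches the object scale.

    An object is easiest to localise where it spans about
    ``_CANONICAL_RATIO`` grid cells; tiny ears therefore land on the finest
    available stride.
    """
    size = math.sqrt(box.area)
    return min(strides,
               key=lambda s: abs(math.log2(max(size / s, 1e-9) / _CANONICAL_RATIO)))


def fit_anchors(labels: list[LabelRecord], strides, seed: int = 0) -> dict:
    """One anchor per level, fit to the sizes of the labels routed there.

    Labels are routed by canonical scale (:func:`route_stride`); each
    level's anchor is the mean (w, h) of its labels — the single-cluster
    k-means solution.  Levels with no routed labels fall back to the overall
    median size (they receive no positives, so the anchor is inert).
    """
    if not labels:
        raise ValidationError("cannot fit anchors without labels")
    wh = np.array([[r.box.width, r.box.height] for r in labels], dtype=float)
    med = np.median(wh, axis=0)
    anchors = {}
    for s in sorted(strides):
        routed = [i for i, r in enumerate(labels)
                  if route_stride(r.box, strides) == s]
        centre = wh[routed].mean(axis=0) if routed else med
        anchors[s] = [tuple(centre)]
    return anchors


def _assign_targets(labels_per_image, model, shape):
    """Positive-cell lists per stride: (image, gy, gx, target box)."""
    cfg = model.config
    targets = {s: [] for s in cfg.strides}
    h, w = shape
    for n, labels in enumerate(labels_per_image):
        for rec in labels:
            box = rec.box
            # canonical-scale routing, then the anchor-IoU floor at the level
            best = route_stride(box, cfg.strides)
            if _wh_iou((box.width, box.height),
                       model.anchors[best][0]) < cfg.anchor_iou:
                continue
            cx, cy = box.center
            nx, ny = w // best, h // best
            gx = min(int(cx / best), nx - 1)
            gy = min(int(cy / best), ny - 1)
            # the decode range spans half a cell beyond the grid cell, so the
            # two nearest neighbour cells also regress this box
            fx, fy = cx / best - gx, cy / best - gy
            cells = [(gy, gx),
                     (gy, gx + (1 if fx > 0.5 else -1)),
                     (gy + (1 if fy > 0.5 else -1), gx)]
            for cy_, cx_ in cells:
                if 0 <= cx_ < nx and 0 <= cy_ < ny:
                    targets[best].append((n, cy_, cx_, box))
    # resolve duplicate claims on one cell: the box whose center is nearest
    # to the cell center wins (deterministic)
    for s, items in targets.items():
        best_by_cell: dict[tuple, tuple] = {}
        for item in items:
            n, gy, gx, box = item
            cx, cy = box.center
            d = math.hypot(cx - (gx + 0.5) * s, cy - (gy + 0.5) * s)
            key = (n, gy, gx)
            if key not in best_by_cell or d < best_by_cell[key][0]:
                best_by_cell[key] = (d, item)
        targets[s] = [entry[1] for _, entry in sorted(best_by_cell.items())]
    return targets


def _decode_cells(box_logits: nn.Tensor, stride: int, anchor, n_idx, gy, gx):
    """Differentiable decode of selected cells to corner tensors.

    Returns (x1, y1, x2, y2, sigmas) where `sigmas` are the four sigmoid
    activations, used for the direct coordinate-regression term.
    """
    aw, ah = anchor
    tx = nn.take(box_logits, (n_idx, np.zeros_like(n_idx), gy, gx))
    ty = nn.take(box_logits, (n_idx, np.ones_like(n_idx), gy, gx))
    tw = nn.take(box_logits, (n_idx, np.full_like(n_idx, 2), gy, gx))
    th = nn.take(box_logits, (n_idx, np.full_like(n_idx, 3), gy, gx))
    sx, sy, sw, sh = (nn.sigmoid(t) for t in (tx, ty, tw, th))
    cx = (sx * 2.0 - 0.5 + gx) * stride
    cy = (sy * 2.0 - 0.5 + gy) * stride
    bw = (sw * 2.0) ** 2 * aw
    bh = (sh * 2.0) ** 2 * ah
    half_w, half_h = bw * 0.5, bh * 0.5
    return (cx - half_w, cy - half_h, cx + half_w, cy + half_h,
            (sx, sy, sw, sh))


def _coord_targets(boxes: list[BBox], stride: int, anchor, gy, gx):
    """Sigmoid-space regression targets for the selected cells."""
    aw, ah = anchor
    t = np.array([[*b.center, b.width, b.height] for b in boxes])
    sx = np.clip((t[:, 0] / stride - gx + 0.5) / 2.0, 1e-4, 1 - 1e-4)
    sy = np.clip((t[:, 1] / stride - gy + 0.5) / 2.0, 1e-4, 1 - 1e-4)
    sw = np.clip(np.sqrt(t[:, 2] / aw) / 2.0, 1e-4, 1 - 1e-4)
    sh = np.clip(np.sqrt(t[:, 3] / ah) / 2.0, 1e-4, 1 - 1e-4)
    return sx, sy, sw, sh


def _iou_tensor(x1, y1, x2, y2, boxes: list[BBox]):
    """Differentiable per-cell (IoU, GIoU) against the target boxes.

    GIoU keeps a useful gradient even when a prediction drifts disjoint from
    its target (plain IoU is flat at zero there).
    """
    t = np.array([b.as_array() for b in boxes])
    ix = nn.minimum(x2, t[:, 2]) - nn.maximum(x1, t[:, 0])
    iy = nn.minimum(y2, t[:, 3]) - nn.maximum(y1, t[:, 1])
    inter = nn.maximum(ix, 0.0) * nn.maximum(iy, 0.0)
    area_p = nn.maximum(x2 - x1, 1e-9) * nn.maximum(y2 - y1, 1e-9)
    area_t = (t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1])
    union = area_p + area_t - inter
    iou_t = inter / union
    ex = nn.maximum(x2, t[:, 2]) - nn.minimum(x1, t[:, 0])
    ey = nn.maximum(y2, t[:, 3]) - nn.minimum(y1, t[:, 1])
    enclose = nn.maximum(ex * ey, 1e-9)
    giou = iou_t - (enclose - union) / enclose
    return iou_t, giou


def _detection_loss(model, outputs, labels_per_image, shape):
    """Box IoU loss + class-balanced objectness BCE, averaged over levels."""
    targets = _assign_targets(labels_per_image, model, shape)
    total = nn.Tensor(np.array(0.0))
    n_levels = len(model.config.strides)
    n_pos_levels = max(1, sum(1 for s in model.config.strides if targets[s]))
    for i, s in enumerate(model.config.strides):
        box_logits, obj_logits = outputs[s]
        items = targets[s]
        obj_target = np.zeros(obj_logits.data.shape)
        # focal-style negative weighting: easy background fades out while
        # confident false positives keep a strong gradient, independent of
        # how many grid cells the level has
        p_neg = 1.0 / (1.0 + np.exp(-obj_logits.data))
        weight = _NEG_FLOOR + p_neg ** 2
        if items:
            n_idx = np.array([it[0] for it in items])
            gy = np.array([it[1] for it in items])
            gx = np.array([it[2] for it in items])
            boxes = [it[3] for it in items]
            x1, y1, x2, y2, sig = _decode_cells(box_logits, s,
                                                model.anchors[s][0],
                                                n_idx, gy, gx)
            cell_iou, cell_giou = _iou_tensor(x1, y1, x2, y2, boxes)
            total = total + (_BOX_WEIGHT * (1.0 - cell_giou).mean()
                             / n_pos_levels)
            # direct sigmoid-space coordinate regression: much better
            # conditioned than the IoU surface, so the short desk-scale
            # training schedule converges; GIoU above does the fine polish
            for pred, target in zip(sig, _coord_targets(boxes, s,
                                                        model.anchors[s][0],
                                                        gy, gx)):
                total = total + (_COORD_WEIGHT * ((pred - target) ** 2).mean()
                                 / n_pos_levels)
            # objectness learns the regression quality: target = detached
            # IoU of the current prediction, so cells that cannot place the
            # box well report low confidence instead of confident junk
            obj_target[n_idx, 0, gy, gx] = np.clip(cell_iou.data, 0.0, 1.0)
            # positives carry a fixed share of the total BCE weight, so the
            # balance is independent of grid area and of how many negatives
            # the focal weighting has already silenced
            n_pos = len(items)
            w_neg_total = float(weight.sum() - weight[n_idx, 0, gy, gx].sum())
            weight[n_idx, 0, gy, gx] = max(
                1.0, (_OBJ_POS_FRACTION / (1.0 - _OBJ_POS_FRACTION))
                * w_neg_total / max(n_pos, 1))
        total = total + nn.bce_with_logits(obj_logits, obj_target,
                                           weight) / n_levels
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_input(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float32)
    if f.ndim == 3:
        f = f.mean(axis=2)
    return (f / 255.0)[None]


def train_detector(model: EarDetector, frames: list[np.ndarray],
                   labels: list[LabelRecord],
                   config: DetectorConfig | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean loss log.

    SGD with momentum under a one-cycle cosine schedule (with a short linear
    warm-up); loss is IoU box regression plus balanced objectness BCE.
    """
    cfg = config or model.config
    by_frame: dict[int, list[LabelRecord]] = {}
    for rec in labels:
        by_frame.setdefault(rec.frame_index, []).append(rec)
    if not by_frame:
        raise ValidationError("no labelled frames to train on")
    if not model.anchors:
        model.anchors = fit_anchors(labels, cfg.strides, seed=cfg.seed)
    shape = np.asarray(frames[0]).shape[:2]
    # verify at least one label can be matched to an anchor cell
    probe = _assign_targets([labels], model, shape)
    if not any(probe.values()):
        raise ValidationError("no positive anchors matchable to any label")
    indices = sorted(by_frame)
    h, w = shape
    # horizontal/vertical flip augmentation: cheap positional diversity that
    # a translation-equivariant detector cannot get from one short clip
    flip_cache: dict[tuple[int, int, int], tuple] = {}

    def flipped(i: int, fh: int, fv: int):
        key = (i, fh, fv)
        if key not in flip_cache:
            frame = np.asarray(frames[i])
            recs = by_frame[i]
            if fh:
                frame = frame[:, ::-1]
                recs = [LabelRecord(r.frame_index, r.class_id,
                                    BBox(w - r.box.x_max, r.box.y_min,
                                         w - r.box.x_min, r.box.y_max),
                                    r.identity) for r in recs]
            if fv:
                frame = frame[::-1]
                recs = [LabelRecord(r.frame_index, r.class_id,
                                    BBox(r.box.x_min, h - r.box.y_max,
                                         r.box.x_max, h - r.box.y_min),
                                    r.identity) for r in recs]
            flip_cache[key] = (frame, recs)
        return flip_cache[key]

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 23]))
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    steps_per_epoch = max(1, math.ceil(len(indices) / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    warmup = max(1, int(cfg.warmup_fraction * total_steps))
    log = get_logger()
    loss_log: list[float] = []
    step = 0
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(indices))
        epoch_losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            batch = [indices[k] for k in order[b0:b0 + cfg.batch_size]]
            flips = rng.integers(0, 2, size=(len(batch), 2))
            pairs = [flipped(i, int(f[0]), int(f[1]))
                     for i, f in zip(batch, flips)]
            x = nn.Tensor(np.stack([_to_input(fr) for fr, _ in pairs]))
            outputs = model(x)
            loss = _detection_loss(model, outputs,
                                   [recs for _, recs in pairs], shape)
            opt.zero_grad()
            loss.backward()
            base = nn.one_cycle_lr(step, total_steps, cfg.learning_rate,
                                   cfg.final_lr_factor)
            opt.lr = base * min(1.0, (step + 1) / warmup)
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
        loss_log.append(float(np.mean(epoch_losses)))
        if epoch % 10 == 0 or epoch == cfg.epochs - 1:
            log.info("detector epoch %d/%d loss %.4f", epoch + 1,
                     cfg.epochs, loss_log[-1])
    model.eval()
    return loss_log


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression by descending confidence."""
    if not (0.0 < iou_threshold <= 1.0):
        raise ValidationError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    kept: list[Detection] = []
    for i in order:
        d = detections[i]
        if all(iou(d.box, k.box) < iou_threshold for k in kept):
            kept.append(d)
    return kept


def detect_ears(model: EarDetector, frame: np.ndarray,
                confidence_threshold: float | None = None,
                nms_iou: float | None = None,
                max_detections: int = 100) -> list[Detection]:
    """Decoded, thresholded, NMS-filtered detections in full-frame pixels."""
    cfg = model.config
    if confidence_threshold is None:
        confidence_threshold = cfg.confidence_threshold
    if nms_iou is None:
        nms_iou = cfg.nms_iou
    h, w = np.asarray(frame).shape[:2]
    model.eval()
    outputs = model(nn.Tensor(_to_input(frame)[None]))
    raw: list[Detection] = []
    for s in cfg.strides:
        box_logits, obj_logits = outputs[s]
        conf = 1.0 / (1.0 + np.exp(-obj_logits.data[0, 0]))
        # sigmoid confidence is strictly below 1, so threshold 1.0 keeps nothing
        ys, xs = np.nonzero(conf >= confidence_threshold)
        aw, ah = model.anchors[s][0]
        for gy, gx in zip(ys, xs):
            t = box_logits.data[0, :, gy, gx]
            sx = 1.0 / (1.0 + np.exp(-t))
            cx = (sx[0] * 2.0 - 0.5 + gx) * s
            cy = (sx[1] * 2.0 - 0.5 + gy) * s
            bw = (sx[2] * 2.0) ** 2 * aw
            bh = (sx[3] * 2.0) ** 2 * ah
            box = BBox(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2)
            raw.append(Detection(box=box.clip(w, h), confidence=float(conf[gy, gx])))
    raw.sort(key=lambda d: -d.confidence)
    return nms(raw[:max_detections], nms_iou)


def evaluate_map(model: EarDetector, frames: list[np.ndarray],
                 labels: list[LabelRecord], thresholds=None,
                 confidence_threshold: float = 0.1) -> float:
    """mAP of the model on labelled frames (default thresholds 0.5:0.9)."""
    from .evaluation import MAP_THRESHOLDS, map_metric, match_detections
    thresholds = thresholds or MAP_THRESHOLDS
    gt = [(r.frame_index, r.box) for r in labels]
    dets = []
    for i, frame in enumerate(frames):
        for d in detect_ears(model, frame,
                             confidence_threshold=confidence_threshold):
            dets.append((i, d.box, d.confidence))
    return map_metric(match_detections(gt, dets, thresholds), thresholds)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: EarDetector, path: str | Path) -> None:
    """Config + weights + format version in one .npz archive."""
    cfg = asdict(model.config)
    cfg["anchors"] = {str(k): [list(a) for a in v]
                      for k, v in model.anchors.items()}
    meta = json.dumps({"format_version": MODEL_FORMAT_VERSION,
                       "kind": "ear_detector", "config": cfg})
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> EarDetector:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("kind") != "ear_detector":
            raise ValidationError(f"{path} is not an ear-detector model file")
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError("unsupported model format version")
        cfg_dict = meta["config"]
        anchors = {int(k): [tuple(a) for a in v]
                   for k, v in cfg_dict.pop("anchors").items()}
        cfg = DetectorConfig(**{**cfg_dict, "anchors": None})
        model = build_network(cfg)
        model.anchors = anchors
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__meta__"})
    model.eval()
    return model
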