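"""Deterministic synthetic open-field videos with full ground truth.

The generator emulates the overhead view of an open-field test: a bright,
featureless floor, one to four dark mouse-like bodies (filled ellipses), and
two small ear disks at the head end of each body, rendered at an intensity
distinct from both floor and body.  Subjects follow smooth random walks with
heading persistence (an Ornstein-Uhlenbeck-like turn process) and reflective
walls, which produces both wall-following and crossing/occlusion events.

Everything is reproducible bitwise from the spec's seed.  Ground truth
carries per-frame body poses, ear boxes, identities and occlusion flags; a
subject is flagged occluded on a frame when its rendered pixel set touches
(8-adjacency) another subject's, which is exactly the condition under which
foreground segmentation merges the two subjects into one blob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import BBox
from .io_formats import (FrameSequence, LabelRecord, TrackRecord,
                         ValidationError, get_logger, write_frames,
                         write_labels, write_tracks)

__all__ = [
    "ArenaSpec",
    "Paths",
    "GroundTruth",
    "simulate_trajectories",
    "render_frames",
    "make_video",
    "crossing_events",
    "write_dataset",
]

EAR_ANGLE = math.radians(35.0)   # ear rays off the heading axis
_TURN_SD = 0.30                  # heading diffusion, radians per frame
_DILATE = np.ones((3, 3), bool)  # 8-adjacency structuring element


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry, population, motion and rendering parameters of one video."""

    width: int = 256
    height: int = 256
    n_subjects: int = 2
    body_axes: tuple[float, float] = (14.0, 7.0)   # (major, minor) semi-axes, px
    ear_radius: float = 3.0
    speed_scale: float = 2.5                       # px / frame
    n_frames: int = 600
    frame_rate: float = 40.0
    noise_sd: float = 2.0                          # 8-bit intensity units
    seed: int = 0
    background_intensity: float = 220.0
    body_intensity: float = 60.0
    ear_intensity: float = 140.0

    def __post_init__(self):
        if not (1 <= self.n_subjects <= 4):
            raise ValidationError("n_subjects must be in [1, 4]")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if min(self.width, self.height, self.ear_radius,
               *self.body_axes, self.frame_rate) <= 0:
            raise ValidationError("all sizes must be positive")
        if self.body_axes[0] < self.body_axes[1]:
            raise ValidationError("body_axes must be (major, minor)")
        if self.ear_radius >= self.body_axes[1]:
            raise ValidationError("ear_radius must be smaller than the minor body axis")
        if 2 * self.margin >= min(self.width, self.height):
            raise ValidationError("subject does not fit in the arena")

    @property
    def margin(self) -> float:
        """Wall margin keeping the full subject (body + ears) inside the frame."""
        return self.body_axes[0] + self.ear_radius + 1.0


@dataclass
class Paths:
    """Simulated per-subject motion: positions (T, n, 2) and headings (T, n)."""

    positions: np.ndarray
    headings: np.ndarray
    seed_used: int


@dataclass
class GroundTruth:
    """Per-frame, per-subject rendering truth for a synthetic video."""

    spec: ArenaSpec
    positions: np.ndarray            # (T, n, 2) body centers
    headings: np.ndarray             # (T, n)
    ear_boxes: list                  # [frame][subject] -> (BBox, BBox)
    ear_centers: np.ndarray          # (T, n, 2, 2) float (x, y)
    occluded: np.ndarray             # (T, n) bool

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.positions.shape[1]

    def track_records(self) -> list[TrackRecord]:
        """Body-center tracks; identities 1..n."""
        return [
            TrackRecord(t, s + 1, float(self.positions[t, s, 0]),
                        float(self.positions[t, s, 1]))
            for t in range(self.n_frames)
            for s in range(self.n_subjects)
        ]

    def label_records(self) -> list[LabelRecord]:
        """Ear boxes as labels; ear identities 2s+1, 2s+2 for subject s."""
        out = []
        for t in range(self.n_frames):
            for s in range(self.n_subjects):
                for e, box in enumerate(self.ear_boxes[t][s]):
                    out.append(LabelRecord(t, 0, box, identity=2 * s + 1 + e))
        return out

    def occlusion_frame_flags(self) -> np.ndarray:
        """(T,) bool: any subject occluded on the frame."""
        return self.occluded.any(axis=1)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 axes: tuple[float, float], angle: float) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse; angle is the major-axis heading."""
    h, w = shape
    cx, cy = center
    a, b = axes
    ca, sa = math.cos(angle), math.sin(angle)
    ex = math.sqrt((a * ca) ** 2 + (b * sa) ** 2)
    ey = math.sqrt((a * sa) ** 2 + (b * ca) ** 2)
    x0, x1 = max(int(cx - ex) - 1, 0), min(int(cx + ex) + 2, w)
    y0, y1 = max(int(cy - ey) - 1, 0), min(int(cy + ey) + 2, h)
    mask = np.zeros(shape, bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    mask[y0:y1, x0:x1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    return ellipse_mask(shape, center, (radius, radius), 0.0)


def ear_centers(spec: ArenaSpec, pos: np.ndarray, heading: float) -> np.ndarray:
    """(2, 2) array of the two ear-disk centers (x, y) for one subject.

    Ears sit on the +-35 degree rays off the heading, near the head focus of
    the body ellipse, pulled in just enough that each disk stays 8-connected
    to the body while still protruding.
    """
    a, b = spec.body_axes
    focal = math.sqrt(max(a * a - b * b, 0.0))
    r_boundary = a * b / math.sqrt((b * math.cos(EAR_ANGLE)) ** 2
                                   + (a * math.sin(EAR_ANGLE)) ** 2)
    d = min(focal, r_boundary + 0.3 * spec.ear_radius)
    d = max(d, r_boundary - 0.2 * spec.ear_radius)
    out = np.empty((2, 2))
    for i, sign in enumerate((+1.0, -1.0)):
        ang = heading + sign * EAR_ANGLE
        out[i] = pos + d * np.array([math.cos(ang), math.sin(ang)])
    return out


def subject_mask(spec: ArenaSpec, pos: np.ndarray, heading: float,
                 shape: tuple[int, int]) -> np.ndarray:
    """Full rendered pixel set of one subject: body ellipse plus two ears."""
    mask = ellipse_mask(shape, tuple(pos), spec.body_axes, heading)
    for c in ear_centers(spec, pos, heading):
        mask |= disk_mask(shape, tuple(c), spec.ear_radius)
    return mask


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _generate_paths(spec: ArenaSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n, T = spec.n_subjects, spec.n_frames
    lo = spec.margin
    hix, hiy = spec.width - 1 - spec.margin, spec.height - 1 - spec.margin
    pos = np.empty((T, n, 2))
    theta = np.empty((T, n))

    # initial placement with pairwise separation where feasible
    placed: list[np.ndarray] = []
    min_sep = 2.5 * spec.body_axes[0]
    for _ in range(n):
        for attempt in range(200):
            p = rng.uniform([lo, lo], [hix, hiy])
            if all(np.hypot(*(p - q)) >= min_sep for q in placed) or attempt == 199:
                placed.append(p)
                break
    pos[0] = np.stack(placed)
    theta[0] = rng.uniform(0, 2 * math.pi, n)

    for t in range(1, T):
        theta[t] = theta[t - 1] + _TURN_SD * rng.standard_normal(n)
        step = spec.speed_scale
        nxt = pos[t - 1] + step * np.stack([np.cos(theta[t]), np.sin(theta[t])], axis=-1)
        for s in range(n):
            x, y = nxt[s]
            th = theta[t, s]
            for _ in range(4):  # reflective walls
                moved = False
                if x < lo:
                    x, th, moved = 2 * lo - x, math.pi - th, True
                elif x > hix:
                    x, th, moved = 2 * hix - x, math.pi - th, True
                if y < lo:
                    y, th, moved = 2 * lo - y, -th, True
                elif y > hiy:
                    y, th, moved = 2 * hiy - y, -th, True
                if not moved:
                    break
            nxt[s] = (x, y)
            theta[t, s] = th
        pos[t] = nxt
    return pos, theta


def compute_occlusion(spec: ArenaSpec, positions: np.ndarray,
                      headings: np.ndarray) -> np.ndarray:
    """(T, n) flags: rendered pixel sets of two subjects touch (8-adjacency).

    Pairs are pre-filtered by a bounding-circle test before any mask is built.
    """
    T, n = positions.shape[:2]
    shape = (spec.height, spec.width)
    reach = spec.body_axes[0] + spec.ear_radius + 1.5
    occ = np.zeros((T, n), bool)
    for t in range(T):
        masks: dict[int, np.ndarray] = {}
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(positions[t, i] - positions[t, j])) > 2 * reach:
                    continue
                for k in (i, j):
                    if k not in masks:
                        masks[k] = subject_mask(spec, positions[t, k],
                                                headings[t, k], shape)
                touch = (ndimage.binary_dilation(masks[i], _DILATE) & masks[j]).any()
                if touch:
                    occ[t, i] = occ[t, j] = True
    return occ


def simulate_trajectories(spec: ArenaSpec) -> Paths:
    """Smooth seeded random-walk paths; guarantees a crossing where expected.

    When two or more subjects roam long enough to plausibly meet
    (speed x duration exceeding the arena diagonal), seeds are retried with
    fixed offsets until at least one frame shows intersecting subjects, and
    the seed finally used is recorded on the result.
    """
    diag = math.hypot(spec.width, spec.height)
    need_crossing = (spec.n_subjects >= 2
                     and spec.speed_scale * spec.n_frames > diag)
    log = get_logger()
    for attempt in range(64):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, attempt]))
        pos, theta = _generate_paths(spec, rng)
        if not need_crossing:
            return Paths(pos, theta, seed_used=spec.seed)
        occ = compute_occlusion(spec, pos, theta)
        if occ.any():
            if attempt:
                log.info("crossing found at seed offset %d", attempt)
            return Paths(pos, theta, seed_used=spec.seed + attempt)
    raise RuntimeError("no crossing event found in 64 seed offsets")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frames(paths: Paths, spec: ArenaSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render the simulated paths into 8-bit frames plus ground truth.

    Bodies are drawn first (identity order), then all ear disks on top, so
    every ground-truth ear box contains pixels at the ear intensity.
    """
    T, n = paths.positions.shape[:2]
    shape = (spec.height, spec.width)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 7]))
    frames: list[np.ndarray] = []
    ear_boxes: list[list[tuple[BBox, BBox]]] = []
    centers = np.empty((T, n, 2, 2))
    for t in range(T):
        canvas = np.full(shape, spec.background_intensity, dtype=np.float64)
        for s in range(n):
            body = ellipse_mask(shape, tuple(paths.positions[t, s]),
                                spec.body_axes, paths.headings[t, s])
            canvas[body] = spec.body_intensity
        frame_boxes: list[tuple[BBox, BBox]] = []
        for s in range(n):
            ec = ear_centers(spec, paths.positions[t, s], paths.headings[t, s])
            centers[t, s] = ec
            boxes = []
            for c in ec:
                disk = disk_mask(shape, tuple(c), spec.ear_radius)
                canvas[disk] = spec.ear_intensity
                ys, xs = np.nonzero(disk)
                boxes.append(BBox(float(xs.min()), float(ys.min()),
                                  float(xs.max() + 1), float(ys.max() + 1)))
            frame_boxes.append(tuple(boxes))
        ear_boxes.append(frame_boxes)
        if spec.noise_sd > 0:
            canvas = canvas + noise_rng.normal(0.0, spec.noise_sd, shape)
        frames.append(np.clip(np.rint(canvas), 0, 255).astype(np.uint8))
    occluded = compute_occlusion(spec, paths.positions, paths.headings)
    seq = FrameSequence(frames=frames, frame_rate=spec.frame_rate)
    truth = GroundTruth(spec=spec, positions=paths.positions,
                        headings=paths.headings, ear_boxes=ear_boxes,
                        ear_centers=centers, occluded=occluded)
    return seq, truth


def make_video(spec: ArenaSpec) -> tuple[FrameSequence, GroundTruth]:
    """Simulate and render in one call."""
    return render_frames(simulate_trajectories(spec), spec)


def crossing_events(occluded_any: np.ndarray) -> int:
    """Number of occlusion episodes (maximal runs of occluded frames)."""
    flags = np.asarray(occluded_any, bool)
    return int(((~np.r_[False, flags[:-1]]) & flags).sum())


def write_dataset(spec: ArenaSpec, out_dir: str | Path) -> GroundTruth:
    """Render a dataset to disk: frames, YOLO labels, track CSV, occlusion CSV."""
    out_dir = Path(out_dir)
    seq, truth = make_video(spec)
    write_frames(seq, out_dir / "frames")
    write_labels(truth.label_records(), out_dir / "labels", spec.width, spec.height)
    write_tracks(truth.track_records(), out_dir / "tracks.csv")
    occ = truth.occluded
    with open(out_dir / "occlusion.csv", "w") as fh:
        fh.write("frame," + ",".join(f"subject_{s+1}" for s in range(occ.shape[1])) + "\n")
        for t in range(occ.shape[0]):
            fh.write(f"{t}," + ",".join(str(int(v)) for v in occ[t]) + "\n")
    return truth
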