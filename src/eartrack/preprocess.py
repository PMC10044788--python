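"""Frame normalisation, background model, blob segmentation and frame classes.

The tracking front end follows the classical pipeline for featureless-arena
video: every frame is linearly rescaled to a common mean intensity (so
illumination drift cancels), a background image is the pixel-wise mean of
evenly subsampled frames, and foreground blobs are 8-connected components of
pixels whose absolute difference from the background exceeds a threshold.
A frame whose blob count equals the declared number of subjects is a
non-occlusion frame; any mismatch (merged subjects, or residual noise blobs
surviving the area filter) marks an occlusion frame.  Maximal runs of equal
frame kind form fragments; each occlusion fragment remembers the adjacent
non-occlusion frames (its flanks) used later to hand identities over.

Automatic ear labelling for single-subject videos uses the double-threshold
scheme: one threshold separates subject from background, a second separates
the (lighter) ears from the body inside the subject's bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BBox
from .io_formats import FrameSequence, LabelRecord, ValidationError, get_logger

__all__ = [
    "NON_OCCLUSION",
    "OCCLUSION",
    "Blob",
    "Fragment",
    "normalize_frame",
    "build_background",
    "segment_blobs",
    "classify_frames",
    "split_fragments",
    "auto_label_ears",
    "label_ear_identities",
    "default_min_blob_area",
]

NON_OCCLUSION = "non_occlusion"
OCCLUSION = "occlusion"

_STRUCT8 = np.ones((3, 3), bool)
_REFERENCE_AREA = 1280 * 720
_REFERENCE_MIN_BLOB = 50


@dataclass
class Blob:
    """A connected set of foreground pixels in one frame."""

    frame_index: int
    pixels: np.ndarray           # (N, 2) int array of (x, y)
    bbox: BBox
    centroid: tuple[float, float]
    area: int

    def flat(self, width: int) -> np.ndarray:
        """Encoded pixel indices (y*width + x), sorted, for set arithmetic."""
        return np.sort(self.pixels[:, 1].astype(np.int64) * width
                       + self.pixels[:, 0])


@dataclass
class Fragment:
    """A maximal run of frames of one kind, inclusive [start, end]."""

    kind: str
    start: int
    end: int
    flank_before: int | None = None
    flank_after: int | None = None

    @property
    def frames(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


def default_min_blob_area(width: int, height: int) -> int:
    """Minimum blob area, scaled from 50 px at 1280x720 by arena area."""
    return max(1, round(_REFERENCE_MIN_BLOB * (width * height) / _REFERENCE_AREA))


def normalize_frame(frame: np.ndarray, reference: float = 128.0) -> np.ndarray:
    """Linearly rescale a frame so its mean intensity equals `reference`."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValidationError("empty frame")
    mean = frame.mean()
    if mean <= 0:
        raise ValidationError("degenerate input: frame mean intensity is zero")
    return frame * (reference / mean)


def build_background(seq: FrameSequence, n_samples: int,
                     transform=None, method: str = "mean") -> np.ndarray:
    """Pixel-wise mean of `n_samples` evenly subsampled frames.

    `transform` (e.g. :func:`normalize_frame`) is applied to each sampled
    frame before averaging; by default frames are averaged as-is.  With
    ``method="median"`` the pixel-wise median is used instead: any pixel a
    subject occupies in fewer than half the samples then takes the true
    background value exactly, which suppresses dwell ghosts.
    """
    if len(seq) == 0:
        raise ValidationError("empty frame sequence")
    if not (1 <= n_samples <= len(seq)):
        raise ValidationError("n_samples must be in [1, number of frames]")
    if method not in ("mean", "median"):
        raise ValidationError(f"unknown background method {method!r}")
    idx = np.unique(np.linspace(0, len(seq) - 1, n_samples).round().astype(int))
    samples = []
    for i in idx:
        f = np.asarray(seq.frames[i], dtype=np.float64)
        samples.append(transform(f) if transform is not None else f)
    stack = np.stack(samples)
    return stack.mean(axis=0) if method == "mean" else np.median(stack, axis=0)


def segment_blobs(frame: np.ndarray, background: np.ndarray, threshold: float,
                  min_blob_area: int = 1, frame_index: int = 0) -> list[Blob]:
    """Foreground blobs: |frame - background| > threshold, 8-connected,
    area >= min_blob_area, sorted by descending area."""
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ValidationError(
            f"frame shape {frame.shape} != background shape {background.shape}")
    if frame.ndim == 3:  # collapse colour to intensity
        frame = frame.mean(axis=2)
        background = background.mean(axis=2)
    fg = np.abs(frame - background) > threshold
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    blobs: list[Blob] = []
    for comp in range(1, n + 1):
        ys, xs = np.nonzero(labels == comp)
        area = len(xs)
        if area < min_blob_area:
            continue
        blobs.append(Blob(
            frame_index=frame_index,
            pixels=np.column_stack([xs, ys]).astype(np.int64),
            bbox=BBox(float(xs.min()), float(ys.min()),
                      float(xs.max() + 1), float(ys.max() + 1)),
            centroid=(float(xs.mean()), float(ys.mean())),
            area=area,
        ))
    blobs.sort(key=lambda b: (-b.area, b.centroid[1], b.centroid[0]))
    return blobs


def classify_frames(blob_counts, n_subjects: int) -> list[str]:
    """Non-occlusion iff the blob count equals the declared subject count."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    return [NON_OCCLUSION if c == n_subjects else OCCLUSION for c in blob_counts]


def split_fragments(kinds: list[str]) -> list[Fragment]:
    """Maximal runs of equal kind; occlusion fragments carry their flanks."""
    if not kinds:
        raise ValidationError("at least one frame is required")
    fragments: list[Fragment] = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            fragments.append(Fragment(kind=kinds[start], start=start, end=i - 1))
            start = i
    for k, frag in enumerate(fragments):
        if frag.kind == OCCLUSION:
            if k > 0:
                frag.flank_before = fragments[k - 1].end
            if k + 1 < len(fragments):
                frag.flank_after = fragments[k + 1].start
    return fragments


def auto_label_ears(seq: FrameSequence, body_threshold: float = 30.0,
                    ear_threshold: float = 60.0, reference: float = 128.0,
                    min_blob_area: int | None = None,
                    background: np.ndarray | None = None,
                    n_background_samples: int = 60) -> list[LabelRecord]:
    """Automatic ear boxes for a single-subject video by double thresholding.

    Per frame the (normalised) image is segmented against the background at
    `body_threshold`; the single body blob's bounding box is cropped and
    re-thresholded at `ear_threshold` (absolute normalised intensity — the
    ears render lighter than the body).  The two largest ear components give
    the boxes, in full-frame coordinates.  Frames yielding a number of ear
    components other than two are skipped and logged.
    """
    log = get_logger()
    if min_blob_area is None:
        min_blob_area = default_min_blob_area(seq.width, seq.height)
    if background is None:
        # median background: the single subject occupies any given pixel in a
        # minority of samples, so its dwell ghost vanishes from the model
        background = build_background(
            seq, min(n_background_samples, len(seq)),
            transform=lambda f: normalize_frame(f, reference),
            method="median")
    labels: list[LabelRecord] = []
    for t, raw in enumerate(seq.frames):
        frame = normalize_frame(raw, reference)
        if frame.ndim == 3:
            frame = frame.mean(axis=2)
        blobs = segment_blobs(frame, background, body_threshold,
                              min_blob_area, frame_index=t)
        if len(blobs) != 1:
            raise ValidationError(
                f"frame {t}: expected a single-subject video, found "
                f"{len(blobs)} blobs")
        body = blobs[0]
        x0, y0 = int(body.bbox.x_min), int(body.bbox.y_min)
        x1, y1 = int(body.bbox.x_max), int(body.bbox.y_max)
        crop = frame[y0:y1, x0:x1]
        bg_crop = background[y0:y1, x0:x1] if background.ndim == 2 \
            else background[y0:y1, x0:x1].mean(axis=2)
        fg = np.abs(crop - bg_crop) > body_threshold
        ear_mask = fg & (crop > ear_threshold)
        comp_labels, n = ndimage.label(ear_mask, structure=_STRUCT8)
        if n != 2:
            log.info("frame %d skipped: %d ear components (expected 2)", t, n)
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp_labels), comp_labels,
                                   index=range(1, n + 1))
        order = np.argsort(sizes)[::-1][:2] + 1
        for comp in order:
            ys, xs = np.nonzero(comp_labels == comp)
            labels.append(LabelRecord(
                frame_index=t, class_id=0,
                box=BBox(float(x0 + xs.min()), float(y0 + ys.min()),
                         float(x0 + xs.max() + 1), float(y0 + ys.max() + 1))))
    return labels


def label_ear_identities(labels: list[LabelRecord]) -> list[LabelRecord]:
    """Assign stable identities (1, 2) to single-subject ear labels.

    On the first labelled frame ears are numbered left-to-right; afterwards
    each frame's pair is matched to the previous frame's by the smaller total
    centroid displacement.  Only valid for two-ears-per-frame label sets.
    """
    by_frame: dict[int, list[LabelRecord]] = {}
    for rec in labels:
        by_frame.setdefault(rec.frame_index, []).append(rec)
    out: list[LabelRecord] = []
    prev: dict[int, tuple[float, float]] = {}
    for t in sorted(by_frame):
        pair = by_frame[t]
        if len(pair) != 2:
            raise ValidationError(f"frame {t}: expected exactly 2 ear labels")
        c = [rec.box.center for rec in pair]
        if not prev:
            order = (0, 1) if c[0][0] <= c[1][0] else (1, 0)
            ids = {order[0]: 1, order[1]: 2}
        else:
            d_keep = (np.hypot(*(np.subtract(c[0], prev[1])))
                      + np.hypot(*(np.subtract(c[1], prev[2]))))
            d_swap = (np.hypot(*(np.subtract(c[0], prev[2])))
                      + np.hypot(*(np.subtract(c[1], prev[1]))))
            ids = {0: 1, 1: 2} if d_keep <= d_swap else {0: 2, 1: 1}
        for i, rec in enumerate(pair):
            out.append(LabelRecord(rec.frame_index, rec.class_id, rec.box,
                                   identity=ids[i]))
            prev[ids[i]] = c[i]
    return out
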