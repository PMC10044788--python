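"""Readers and writers for frames, label files, track files and run configuration.

File dialects
-------------
* Frames: a directory of numbered PNG/JPEG/TIFF images (sorted by name), or a
  single multi-frame image file.  Pixel origin is the top-left corner, x
  rightward, y downward, 0-based.
* Labels: one text file per frame, YOLO convention — rows
  ``class cx cy w h [id]`` with center/size normalised to [0, 1].
* Tracks: CSV with header ``frame,id,x,y,conf``; frame indices 0-based.
* Config: flat YAML key/value mapping; missing keys take documented defaults.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import BBox

__all__ = [
    "FormatError",
    "ValidationError",
    "ParseError",
    "FrameSequence",
    "LabelRecord",
    "TrackRecord",
    "Config",
    "read_frames",
    "write_frames",
    "write_tracks",
    "read_tracks",
    "write_labels",
    "read_labels",
    "load_config",
    "get_logger",
    "setup_logging",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


class FormatError(RuntimeError):
    """Unreadable or unsupported file format."""


class ValidationError(ValueError):
    """Data violates a declared invariant."""


class ParseError(ValueError):
    """Malformed row in a text file; message carries the line number."""


def get_logger(name: str = "eartrack") -> logging.Logger:
    return logging.getLogger(name)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Timestamped, level-filtered logging to stderr and an optional file."""
    logger = logging.getLogger("eartrack")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """Ordered intensity images with frame rate and pixel geometry."""

    frames: list[np.ndarray]
    frame_rate: float

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if not self.frames:
            raise ValidationError("empty frame sequence")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValidationError(
                    f"frame {i} has shape {f.shape}, expected {shape}")

    @property
    def height(self) -> int:
        return self.frames[0].shape[0]

    @property
    def width(self) -> int:
        return self.frames[0].shape[1]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class LabelRecord:
    """One annotated object (class 0 = ear) in one frame."""

    frame_index: int
    class_id: int
    box: BBox
    identity: int | None = None

    def __post_init__(self):
        if self.identity is not None and self.identity < 1:
            raise ValidationError("identity must be >= 1 when present")


@dataclass(frozen=True)
class TrackRecord:
    """One identity's centroid in one frame."""

    frame_index: int
    identity: int
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError("confidence must be in [0, 1]")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """All pipeline tunables with their documented defaults.

    Training defaults (batch size 8, 50 epochs, initial learning rate 0.01,
    final one-cycle factor 0.2, SGD momentum 0.937) are the ear-detector
    settings the method was published with; the desk-scale tests override
    the budget-sized ones (epochs, widths) explicitly.
    """

    seed: int = 0
    n_subjects: int = 2
    frame_rate: float = 30.0
    width: int = 1280
    height: int = 720                 # 960 is equally accepted; see docs/methods.md

    # preprocessing (thresholds apply on the mean-128 normalised scale)
    reference_intensity: float = 128.0
    background_samples: int = 20
    blob_threshold: float = 30.0
    min_blob_area: int = 0            # 0 = auto-scale from arena area
    body_threshold: float = 30.0
    ear_threshold: float = 60.0

    # detector
    improved_neck: bool = True
    base_width: int = 8
    anchors_per_level: int = 1
    confidence_threshold: float = 0.5
    nms_iou: float = 0.45

    # training
    batch_size: int = 8
    epochs: int = 50
    learning_rate: float = 0.01
    final_lr_factor: float = 0.2
    momentum: float = 0.937

    # siamese
    crop_size: int = 32
    margin: float = 1.0
    neg_gap_seconds: float = 60.0
    min_score: float = 0.2

    # evaluation
    match_radius: float = 40.0
    drift_radius: float = 14.0
    mapping_window: int = 30

    # behaviour
    px_per_cm: float = 1.0
    block_seconds: float = 300.0

    # synthetic arena (pipeline demo conditions)
    arena_width: int = 256
    arena_height: int = 256
    body_major: float = 14.0          # semi-axis, px
    body_minor: float = 7.0
    ear_radius: float = 3.0
    speed_scale: float = 2.5          # px/frame
    n_frames: int = 600
    noise_sd: float = 2.0
    train_video_frames: int = 480     # single-subject clip for model training
    train_stride: int = 8             # keep 1 frame in `train_stride`
    siamese_epochs: int = 30
    n_pairs: int = 400                # positives (and negatives) for training


def load_config(path: str | Path | None) -> Config:
    """Load a flat YAML config; missing keys default, unknown keys warn."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must be a flat key/value mapping")
    known = {f.name: f for f in dataclasses.fields(Config)}
    log = get_logger()
    for key, value in raw.items():
        if key not in known:
            log.warning("unknown config key %r ignored", key)
            continue
        target = known[key].type
        default = getattr(cfg, key)
        try:
            if isinstance(default, bool):
                if not isinstance(value, bool):
                    raise TypeError
                coerced = value
            elif isinstance(default, int):
                if isinstance(value, bool) or (isinstance(value, float)
                                               and not float(value).is_integer()):
                    raise TypeError
                coerced = int(value)
            elif isinstance(default, float):
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise TypeError
                coerced = float(value)
            else:
                coerced = type(default)(value)
        except (TypeError, ValueError):
            raise ValidationError(
                f"type mismatch for config key {key!r}: expected {target}, "
                f"got {value!r}") from None
        setattr(cfg, key, coerced)
    return cfg


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def read_frames(path: str | Path, stride: int = 1,
                frame_rate: float | None = None) -> FrameSequence:
    """Read every `stride`-th frame from a directory of images or one file.

    The recorded frame rate is divided by the stride, so a 60 fps source
    read with stride 3 yields an effective 20 fps sequence.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FormatError(f"no image files found in {path}")
        frames = []
        for p in files[::stride]:
            try:
                frames.append(np.asarray(iio.imread(p)))
            except Exception as exc:  # noqa: BLE001 - backend-specific errors
                raise FormatError(f"unreadable image {p}: {exc}") from exc
        rate = frame_rate if frame_rate is not None else 30.0
    else:
        try:
            raw = [np.asarray(f) for f in iio.imiter(path)]
        except Exception:
            try:
                vol = np.asarray(iio.imread(path))
                raw = list(vol) if vol.ndim >= 3 and vol.shape[-1] not in (3, 4) else [vol]
            except Exception as exc:  # noqa: BLE001
                raise FormatError(f"unreadable media file {path}: {exc}") from exc
        if not raw:
            raise FormatError(f"no frames decoded from {path}")
        frames = raw[::stride]
        rate = frame_rate if frame_rate is not None else 30.0
    return FrameSequence(frames=frames, frame_rate=rate / stride)


def write_frames(seq: FrameSequence, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        p = out_dir / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

_TRACK_HEADER = ["frame", "id", "x", "y", "conf"]


def write_tracks(records: list[TrackRecord], path: str | Path) -> None:
    """Write sorted track records as CSV; duplicates are rejected."""
    _check_track_dupes(records)
    records = sorted(records, key=lambda r: (r.frame_index, r.identity))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRACK_HEADER)
        for r in records:
            writer.writerow([r.frame_index, r.identity,
                             f"{r.x:.4f}", f"{r.y:.4f}", f"{r.confidence:.4f}"])


def read_tracks(path: str | Path) -> list[TrackRecord]:
    records: list[TrackRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _TRACK_HEADER:
            raise ParseError(f"{path}: line 1: expected header {','.join(_TRACK_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append(TrackRecord(int(row[0]), int(row[1]),
                                           float(row[2]), float(row[3]), float(row[4])))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed row {row!r}") from exc
    _check_track_dupes(records)
    return records


def _check_track_dupes(records: list[TrackRecord]) -> None:
    seen = set()
    for r in records:
        key = (r.frame_index, r.identity)
        if key in seen:
            raise ValidationError(f"duplicate track record for frame {r.frame_index}, "
                                  f"identity {r.identity}")
        seen.add(key)


# ---------------------------------------------------------------------------
# labels (YOLO dialect, one file per frame)
# ---------------------------------------------------------------------------

def write_labels(labels: list[LabelRecord], out_dir: str | Path,
                 width: int, height: int, prefix: str = "frame") -> list[Path]:
    """One ``<prefix>_<frame:06d>.txt`` per frame, rows ``class cx cy w h [id]``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_frame: dict[int, list[LabelRecord]] = {}
    for rec in labels:
        by_frame.setdefault(rec.frame_index, []).append(rec)
    paths = []
    for frame_index in sorted(by_frame):
        p = out_dir / f"{prefix}_{frame_index:06d}.txt"
        with open(p, "w") as fh:
            for rec in by_frame[frame_index]:
                b = rec.box
                cx, cy = b.center
                row = (f"{rec.class_id} {cx / width:.6f} {cy / height:.6f} "
                       f"{b.width / width:.6f} {b.height / height:.6f}")
                if rec.identity is not None:
                    row += f" {rec.identity}"
                fh.write(row + "\n")
        paths.append(p)
    return paths


def read_labels(label_dir: str | Path, width: int, height: int) -> list[LabelRecord]:
    label_dir = Path(label_dir)
    records: list[LabelRecord] = []
    for p in sorted(label_dir.glob("*.txt")):
        try:
            frame_index = int(p.stem.rsplit("_", 1)[-1])
        except ValueError as exc:
            raise ParseError(f"{p}: cannot parse frame index from filename") from exc
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) not in (5, 6):
                    raise ParseError(f"{p}: line {lineno}: expected 5 or 6 fields")
                try:
                    cls = int(parts[0])
                    cx, cy, w, h = (float(v) for v in parts[1:5])
                    ident = int(parts[5]) if len(parts) == 6 else None
                except ValueError as exc:
                    raise ParseError(f"{p}: line {lineno}: malformed row") from exc
                box = BBox((cx - w / 2) * width, (cy - h / 2) * height,
                           (cx + w / 2) * width, (cy + h / 2) * height)
                records.append(LabelRecord(frame_index, cls, box, ident))
    return records
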