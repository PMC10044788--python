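"""Identity propagation across non-occlusion frames by maximal blob overlap.

At high frame rates a subject barely moves between adjacent frames, so the
blob sharing the most pixels with a previous-frame blob inherits its
identity.  Because a per-blob "most overlap" rule is ambiguous when two
blobs claim the same predecessor, the assignment is solved globally as an
optimal one-to-one matching on shared-pixel counts, which enforces the
one-blob-one-individual model.  Ties are broken by larger IoU, then by
pairing lower incumbent identities with earlier (larger-area) blobs; blobs
with no overlap at all fall back to nearest-centroid matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import iou
from .io_formats import TrackRecord, ValidationError, get_logger
from .preprocess import Blob, Fragment

__all__ = ["BlobTrack", "propagate_ids", "track_fragment", "tracks_to_records"]

_IOU_WEIGHT = 0.45      # < 1: an integer overlap difference always dominates
_PREF_EPS = 1e-6        # deterministic tie-break on remaining degeneracy
_DIST_EPS = 1e-4        # nearest-centroid fallback weight for zero overlap


@dataclass
class BlobTrack:
    """One identity's blob per frame over a non-occlusion fragment."""

    identity: int
    blobs: dict[int, Blob] = field(default_factory=dict)

    def centroid(self, frame_index: int) -> tuple[float, float]:
        return self.blobs[frame_index].centroid


def _overlap_count(a: Blob, b: Blob, width: int) -> int:
    if (a.bbox.x_max <= b.bbox.x_min or b.bbox.x_max <= a.bbox.x_min
            or a.bbox.y_max <= b.bbox.y_min or b.bbox.y_max <= a.bbox.y_min):
        return 0
    return len(np.intersect1d(a.flat(width), b.flat(width), assume_unique=True))


def propagate_ids(prev_blobs: list[Blob], prev_ids: list[int],
                  next_blobs: list[Blob], width: int = 1 << 16) -> list[int]:
    """Identities for `next_blobs`, inherited by maximal-overlap matching.

    Returns a list aligned with `next_blobs`.  `width` is the frame width
    used to encode pixel coordinates (any upper bound works).
    """
    if len(prev_blobs) != len(next_blobs) or len(prev_blobs) != len(prev_ids):
        raise ValidationError("propagate_ids requires equally many previous "
                              "and next blobs, one per subject")
    n = len(prev_blobs)
    overlap = np.zeros((n, n))
    score = np.zeros((n, n))
    diag = 1.0
    cents_p = np.array([b.centroid for b in prev_blobs])
    cents_n = np.array([b.centroid for b in next_blobs])
    if n > 1:
        diag = max(np.ptp(np.vstack([cents_p, cents_n]), axis=0).max(), 1.0)
    id_rank = np.argsort(np.argsort(prev_ids))  # rank of each incumbent id
    for i, pb in enumerate(prev_blobs):
        for j, nb in enumerate(next_blobs):
            ov = _overlap_count(pb, nb, width)
            overlap[i, j] = ov
            dist = float(np.hypot(*(cents_p[i] - cents_n[j])))
            score[i, j] = (ov
                           + _IOU_WEIGHT * iou(pb.bbox, nb.bbox)
                           + _PREF_EPS * (n - id_rank[i]) * (n - j)
                           - _DIST_EPS * dist / diag)
    rows, cols = linear_sum_assignment(-score)
    out = [0] * n
    zero_overlap = False
    for i, j in zip(rows, cols):
        out[j] = prev_ids[i]
        if overlap[i, j] == 0:
            zero_overlap = True
    if zero_overlap:
        get_logger().warning("zero blob overlap for some subject; "
                             "fell back to nearest-centroid matching")
    return out


def track_fragment(fragment: Fragment, blobs_per_frame: dict[int, list[Blob]],
                   seed_ids: list[int] | None = None,
                   width: int = 1 << 16) -> list[BlobTrack]:
    """Frame-by-frame identity propagation over one non-occlusion fragment.

    `seed_ids` aligns with the first frame's blobs (as ordered by the
    segmenter, descending area); absent, identities are 1..n in that order.
    """
    frames = list(fragment.frames)
    n = None
    for t in frames:
        blobs = blobs_per_frame.get(t)
        if blobs is None:
            raise ValidationError(f"no blobs provided for frame {t}")
        if n is None:
            n = len(blobs)
        elif len(blobs) != n:
            raise ValidationError(
                f"frame {t} has {len(blobs)} blobs inside a non-occlusion "
                f"fragment that started with {n}")
    first = blobs_per_frame[frames[0]]
    if seed_ids is None:
        seed_ids = list(range(1, len(first) + 1))
    if len(seed_ids) != len(first):
        raise ValidationError("seed_ids must align with the first frame's blobs")
    tracks = {ident: BlobTrack(identity=ident) for ident in seed_ids}
    ids = list(seed_ids)
    prev = first
    for ident, blob in zip(ids, prev):
        tracks[ident].blobs[frames[0]] = blob
    for t in frames[1:]:
        nxt = blobs_per_frame[t]
        ids = propagate_ids(prev, ids, nxt, width)
        for ident, blob in zip(ids, nxt):
            tracks[ident].blobs[t] = blob
        prev = nxt
    return [tracks[i] for i in sorted(tracks)]


def tracks_to_records(tracks: list[BlobTrack]) -> list[TrackRecord]:
    records = [
        TrackRecord(t, trk.identity, blob.centroid[0], blob.centroid[1])
        for trk in tracks
        for t, blob in sorted(trk.blobs.items())
    ]
    records.sort(key=lambda r: (r.frame_index, r.identity))
    return records
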