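"""Fusing occlusion and non-occlusion fragment tracks into global trajectories.

Non-occlusion fragments carry blob tracks with fragment-local identities;
occlusion fragments carry per-frame individual positions from ear tracking,
also with local labels, covering the fragment plus one flanking
non-occlusion frame on each side.  On a flank frame both labellings coexist,
so local labels can be reconciled: each ear-track individual is matched to
the blob identity whose mask contains its position (falling back to nearest
centroid), and the composition of the two flank matchings relabels the next
fragment.  When the two flanks of one fragment disagree, the earlier flank
wins and the disagreement is logged.  Individuals unmatched on both flanks
leave an explicit identity gap — positions are never interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import TrackRecord, ValidationError, get_logger
from .overlap_tracker import BlobTrack
from .preprocess import Blob, Fragment, NON_OCCLUSION, OCCLUSION

__all__ = ["Trajectory", "link_fragments", "trajectories_to_records",
           "match_positions_to_blobs"]

SOURCE_BLOB = "blob"
SOURCE_EAR = "ear"
SOURCE_GAP = "gap"


@dataclass
class Trajectory:
    """One individual's per-frame position over the full video."""

    identity: int
    positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    sources: dict[int, str] = field(default_factory=dict)

    def gap_frames(self) -> list[int]:
        return sorted(t for t, s in self.sources.items() if s == SOURCE_GAP)


def match_positions_to_blobs(positions: dict[int, tuple[float, float]],
                             blobs: list[Blob], blob_ids: list[int]) -> dict[int, int]:
    """Match labelled positions to identified blobs on one (flank) frame.

    A position inside a blob's pixel mask costs nothing; otherwise the cost
    is the centroid distance.  Returns {position label -> blob identity}
    from the optimal one-to-one matching.
    """
    if not positions or not blobs:
        return {}
    labels = sorted(positions)
    cost = np.zeros((len(labels), len(blobs)))
    for i, lab in enumerate(labels):
        x, y = positions[lab]
        for j, blob in enumerate(blobs):
            inside = (blob.bbox.x_min <= x < blob.bbox.x_max
                      and blob.bbox.y_min <= y < blob.bbox.y_max)
            if inside:
                px = np.round([x, y]).astype(int)
                inside = bool((blob.pixels == px).all(axis=1).any())
            cost[i, j] = 0.0 if inside else float(
                np.hypot(x - blob.centroid[0], y - blob.centroid[1]))
    rows, cols = linear_sum_assignment(cost)
    return {labels[i]: blob_ids[j] for i, j in zip(rows, cols)}


def _fragment_blob_lookup(tracks: list[BlobTrack], frame: int):
    blobs, ids = [], []
    for trk in tracks:
        if frame in trk.blobs:
            blobs.append(trk.blobs[frame])
            ids.append(trk.identity)
    return blobs, ids


def link_fragments(fragments: list[Fragment],
                   blob_tracks: dict[int, list[BlobTrack]],
                   ear_tracks: dict[int, dict[int, dict[int, tuple[float, float]]]],
                   n_subjects: int) -> tuple[list[Trajectory], dict]:
    """Combine per-fragment tracks into global per-individual trajectories.

    `blob_tracks` maps a non-occlusion fragment's index (position in
    `fragments`) to its locally-identified blob tracks; `ear_tracks` maps an
    occlusion fragment's index to {frame -> {local individual -> (x, y)}}
    covering its flank frames.  Returns the trajectories (global identities
    1..n) and a per-fragment linkage report for audit.
    """
    log = get_logger()
    non_occ = [k for k, f in enumerate(fragments) if f.kind == NON_OCCLUSION]
    if not non_occ:
        raise ValidationError("no non-occlusion fragment to anchor identities")
    trajectories = {i: Trajectory(identity=i) for i in range(1, n_subjects + 1)}
    report: dict[str, dict] = {}
    # global mapping of each non-occlusion fragment's local ids
    mappings: dict[int, dict[int, int]] = {}
    first = non_occ[0]
    mappings[first] = {t.identity: t.identity for t in blob_tracks[first]}

    def write_blob_fragment(k: int) -> None:
        m = mappings[k]
        for trk in blob_tracks[k]:
            g = m.get(trk.identity)
            if g is None:
                continue
            for t, blob in trk.blobs.items():
                trajectories[g].positions[t] = blob.centroid
                trajectories[g].sources[t] = SOURCE_BLOB

    write_blob_fragment(first)
    last_known: dict[int, tuple[float, float]] = {
        t.identity: t.blobs[max(t.blobs)].centroid for t in blob_tracks[first]}

    for k in range(len(fragments)):
        frag = fragments[k]
        if frag.kind != OCCLUSION:
            continue
        ears = ear_tracks.get(k, {})
        entry: dict = {"fragment": [frag.start, frag.end]}
        m_before: dict[int, int] = {}
        m_after_local: dict[int, int] = {}
        prev_idx = k - 1 if k > 0 and fragments[k - 1].kind == NON_OCCLUSION else None
        next_idx = k + 1 if k + 1 < len(fragments) else None
        if prev_idx is not None and frag.flank_before is not None \
                and frag.flank_before in ears and prev_idx in mappings:
            blobs, local_ids = _fragment_blob_lookup(blob_tracks[prev_idx],
                                                     frag.flank_before)
            global_ids = [mappings[prev_idx][i] for i in local_ids]
            m_before = match_positions_to_blobs(ears[frag.flank_before],
                                                blobs, global_ids)
        if next_idx is not None and frag.flank_after is not None \
                and frag.flank_after in ears and next_idx < len(fragments):
            blobs, local_ids = _fragment_blob_lookup(blob_tracks.get(next_idx, []),
                                                     frag.flank_after)
            m_after_local = match_positions_to_blobs(ears[frag.flank_after],
                                                     blobs, local_ids)
        # label the occlusion frames: earlier flank wins
        if m_before:
            ind_to_global = dict(m_before)
        elif m_after_local and next_idx is not None:
            # seed global labels through the following fragment instead: its
            # locals become globals via continuity with last known positions
            m_next = _seed_by_continuity(blob_tracks.get(next_idx, []),
                                         fragments[next_idx].start, last_known,
                                         n_subjects)
            mappings[next_idx] = m_next
            ind_to_global = {ind: m_next[loc]
                             for ind, loc in m_after_local.items()
                             if loc in m_next}
        else:
            ind_to_global = {}
            log.warning("occlusion fragment %d-%d unlinked on both flanks",
                        frag.start, frag.end)
        entry["individual_to_global"] = {str(i): g
                                         for i, g in ind_to_global.items()}
        for t in frag.frames:
            present = set()
            for ind, pos in ears.get(t, {}).items():
                g = ind_to_global.get(ind)
                if g is None:
                    continue
                trajectories[g].positions[t] = pos
                trajectories[g].sources[t] = SOURCE_EAR
                present.add(g)
                last_known[g] = pos
            for g in trajectories:
                if g not in present:
                    trajectories[g].sources[t] = SOURCE_GAP
        # derive the next fragment's mapping from the after-flank matching
        if next_idx is not None and next_idx not in mappings \
                and fragments[next_idx].kind == NON_OCCLUSION:
            m_next = {}
            if m_before and m_after_local:
                for ind, g in ind_to_global.items():
                    if ind in m_after_local:
                        m_next[m_after_local[ind]] = g
            if len(m_next) != n_subjects:
                fallback = _seed_by_continuity(blob_tracks.get(next_idx, []),
                                               fragments[next_idx].start,
                                               last_known, n_subjects)
                if m_next and m_next != {
                        loc: fallback[loc] for loc in m_next if loc in fallback}:
                    log.warning("flank disagreement across fragment %d-%d; "
                                "earlier flank kept where available",
                                frag.start, frag.end)
                for loc, g in fallback.items():
                    m_next.setdefault(loc, g)
                used = set()
                for loc in sorted(m_next):
                    if m_next[loc] in used:  # keep bijectivity
                        m_next = fallback
                        break
                    used.add(m_next[loc])
            mappings[next_idx] = m_next
            entry["next_fragment_mapping"] = {str(a): b
                                              for a, b in m_next.items()}
        report[f"fragment_{k}"] = entry

    # write remaining non-occlusion fragments and refresh last positions
    for k in non_occ:
        if k not in mappings:
            mappings[k] = _seed_by_continuity(blob_tracks.get(k, []),
                                              fragments[k].start, last_known,
                                              n_subjects)
        if k != first:
            write_blob_fragment(k)
        for trk in blob_tracks.get(k, []):
            g = mappings[k].get(trk.identity)
            if g is not None:
                last_known[g] = trk.blobs[max(trk.blobs)].centroid
    return [trajectories[i] for i in sorted(trajectories)], report


def _seed_by_continuity(tracks: list[BlobTrack], frame: int,
                        last_known: dict[int, tuple[float, float]],
                        n_subjects: int) -> dict[int, int]:
    """Fallback local->global mapping by nearest centroid to last positions."""
    if not tracks:
        return {}
    local_ids, cents = [], []
    for trk in tracks:
        if frame in trk.blobs:
            local_ids.append(trk.identity)
            cents.append(trk.blobs[frame].centroid)
    globals_ = sorted(last_known) or list(range(1, n_subjects + 1))
    if not last_known:
        return {loc: g for loc, g in zip(local_ids, globals_)}
    cost = np.array([[np.hypot(c[0] - last_known[g][0], c[1] - last_known[g][1])
                      for g in globals_] for c in cents])
    rows, cols = linear_sum_assignment(cost)
    return {local_ids[i]: globals_[j] for i, j in zip(rows, cols)}


def trajectories_to_records(trajectories: list[Trajectory]) -> list[TrackRecord]:
    records = [
        TrackRecord(t, traj.identity, x, y)
        for traj in trajectories
        for t, (x, y) in sorted(traj.positions.items())
    ]
    records.sort(key=lambda r: (r.frame_index, r.identity))
    return records


def write_linkage_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
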