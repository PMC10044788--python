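"""End-to-end orchestration: simulate, preprocess, train, track, link,
evaluate and analyse, under one config and one seed.

The pipeline mirrors the method's own workflow: a single-subject clip is
auto-labelled by double thresholding and used to train the ear detector and
the dual-Siamese similarity model; the multi-subject target video is then
split into occlusion and non-occlusion fragments, tracked by blob overlap
where subjects are separate and by ear detection + similarity assignment
where they occlude, and the fragments are linked into global trajectories.
Every stage's artifact is persisted and individually re-loadable; a single
global seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ear_detector import (DetectorConfig, build_network, detect_ears,
                           load_model, save_model, train_detector)
from .evaluation import icr, mota, score_tracks
from .io_formats import (Config, FrameSequence, LabelRecord, TrackRecord,
                         ValidationError, get_logger, write_labels,
                         write_tracks)
from .linker import (Trajectory, link_fragments, trajectories_to_records,
                     write_linkage_report)
from .overlap_tracker import BlobTrack, track_fragment
from .preprocess import (Blob, Fragment, NON_OCCLUSION, OCCLUSION,
                         auto_label_ears, build_background, classify_frames,
                         default_min_blob_area, label_ear_identities,
                         normalize_frame, segment_blobs, split_fragments)
from .siamese_id import (EarObservation, SiameseConfig, SimilarityModel,
                         assign_identities, extract_observation,
                         group_ears_to_individuals, load_similarity_model,
                         make_pairs, save_similarity_model, train_similarity)
from .synthetic_arena import ArenaSpec, GroundTruth, make_video, write_dataset

__all__ = [
    "PipelineRun",
    "arena_from_config",
    "preprocess_video",
    "train_models",
    "track_video",
    "run_pipeline",
]

# fixed per-stage seed offsets: stage-level reproducibility without coupling
_SEED_TRAIN_VIDEO = 1009
_SEED_DETECTOR = 2003
_SEED_SIAMESE = 3001


@dataclass
class PipelineRun:
    """Artifacts, metrics and timings of one end-to-end run."""

    config: dict
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)


def arena_from_config(config: Config, n_subjects: int | None = None,
                      n_frames: int | None = None, seed: int | None = None) -> ArenaSpec:
    return ArenaSpec(
        width=config.arena_width, height=config.arena_height,
        n_subjects=n_subjects if n_subjects is not None else config.n_subjects,
        body_axes=(config.body_major, config.body_minor),
        ear_radius=config.ear_radius, speed_scale=config.speed_scale,
        n_frames=n_frames if n_frames is not None else config.n_frames,
        frame_rate=config.frame_rate, noise_sd=config.noise_sd,
        seed=seed if seed is not None else config.seed)


# ---------------------------------------------------------------------------
# stage: preprocess
# ---------------------------------------------------------------------------

def preprocess_video(seq: FrameSequence, config: Config):
    """Normalise, model the background, segment blobs and classify frames."""
    min_area = config.min_blob_area or default_min_blob_area(seq.width, seq.height)
    background = build_background(
        seq, min(config.background_samples, len(seq)),
        transform=lambda f: normalize_frame(f, config.reference_intensity),
        method="median")
    blobs_per_frame: dict[int, list[Blob]] = {}
    for t, raw in enumerate(seq.frames):
        frame = normalize_frame(raw, config.reference_intensity)
        blobs_per_frame[t] = segment_blobs(frame, background,
                                           config.blob_threshold, min_area,
                                           frame_index=t)
    counts = [len(blobs_per_frame[t]) for t in range(len(seq))]
    kinds = classify_frames(counts, config.n_subjects)
    fragments = split_fragments(kinds)
    return blobs_per_frame, kinds, fragments, background


# ---------------------------------------------------------------------------
# stage: training
# ---------------------------------------------------------------------------

def train_models(config: Config, train_seq: FrameSequence | None = None):
    """Train detector + similarity model from a single-subject clip.

    The clip is auto-labelled by double thresholding; every
    ``train_stride``-th frame enters detector training, and adjacent kept
    frames provide positive Siamese pairs (the effective frame rate drops by
    the stride accordingly).
    """
    log = get_logger()
    if train_seq is None:
        spec = arena_from_config(config, n_subjects=1,
                                 n_frames=config.train_video_frames,
                                 seed=(config.seed + _SEED_TRAIN_VIDEO) & 0x7FFFFFFF)
        train_seq, _ = make_video(spec)
    labels = label_ear_identities(auto_label_ears(
        train_seq, body_threshold=config.body_threshold,
        ear_threshold=config.ear_threshold,
        reference=config.reference_intensity))
    kept = sorted({r.frame_index for r in labels})[::config.train_stride]
    kept_set = {f: k for k, f in enumerate(kept)}
    det_frames = [train_seq.frames[f] for f in kept]
    det_labels = [LabelRecord(kept_set[r.frame_index], r.class_id, r.box,
                              r.identity)
                  for r in labels if r.frame_index in kept_set]
    det_cfg = DetectorConfig(
        improved=config.improved_neck, width=config.base_width,
        confidence_threshold=config.confidence_threshold,
        nms_iou=config.nms_iou, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        final_lr_factor=config.final_lr_factor, momentum=config.momentum,
        seed=(config.seed + _SEED_DETECTOR) & 0x7FFFFFFF)
    detector = build_network(det_cfg)
    det_log = train_detector(detector, det_frames, det_labels, det_cfg)
    log.info("detector trained: loss %.3f -> %.3f", det_log[0], det_log[-1])

    # Siamese pairs from the same auto-labelled clip at the full frame rate:
    # positive pairs then carry tracking-time adjacency displacements
    obs = [extract_observation(train_seq.frames[r.frame_index], r.box,
                               r.frame_index, crop_size=config.crop_size,
                               identity=r.identity)
           for r in labels]
    rate = train_seq.frame_rate
    gap = min(config.neg_gap_seconds,
              0.25 * len(train_seq) / rate)  # short clips shrink the gap
    pairs = make_pairs(obs, frame_rate=rate, neg_gap_seconds=gap,
                       n_pos=min(config.n_pairs, _max_positives(obs)),
                       n_neg=config.n_pairs,
                       seed=(config.seed + _SEED_SIAMESE) & 0x7FFFFFFF)
    sim_cfg = SiameseConfig(crop_size=config.crop_size, margin=config.margin,
                            epochs=config.siamese_epochs,
                            momentum=config.momentum,
                            seed=(config.seed + _SEED_SIAMESE) & 0x7FFFFFFF)
    sim_model = SimilarityModel(sim_cfg)
    sim_log = train_similarity(sim_model, pairs, sim_cfg)
    log.info("similarity model trained: loss %.3f -> %.3f",
             sim_log[0], sim_log[-1])
    return detector, sim_model


def _max_positives(obs: list[EarObservation]) -> int:
    by_id: dict[int, list[int]] = {}
    for o in obs:
        by_id.setdefault(o.identity, []).append(o.frame_index)
    total = 0
    for frames in by_id.values():
        frames.sort()
        total += sum(1 for a, b in zip(frames, frames[1:]) if b - a == 1)
    return total


# ---------------------------------------------------------------------------
# stage: tracking
# ---------------------------------------------------------------------------

def _observations_for_frame(seq, detector, t, config) -> list[EarObservation]:
    dets = detect_ears(detector, seq.frames[t],
                       confidence_threshold=config.confidence_threshold,
                       nms_iou=config.nms_iou)
    return [extract_observation(seq.frames[t], d.box, t,
                                crop_size=config.crop_size)
            for d in dets]


def _seed_ears_from_blobs(observations: list[EarObservation],
                          blobs: list[Blob], local_ids: list[int]):
    """Attach ear identities (2i-1, 2i per individual i) at a flank frame.

    Each blob owns up to two ears: detections are matched to duplicated blob
    slots by centroid distance (containment in the blob's bounding box wins).
    Returns (seeded observations, ear_id -> individual map).
    """
    from dataclasses import replace
    from scipy.optimize import linear_sum_assignment
    if not observations or not blobs:
        return [], {}
    slots = [(j, k) for j in range(len(blobs)) for k in range(2)]
    cost = np.zeros((len(observations), len(slots)))
    for i, o in enumerate(observations):
        x, y = o.centroid
        for c, (j, _) in enumerate(slots):
            b = blobs[j]
            inside = (b.bbox.x_min <= x < b.bbox.x_max
                      and b.bbox.y_min <= y < b.bbox.y_max)
            d = np.hypot(x - b.centroid[0], y - b.centroid[1])
            cost[i, c] = d * (0.1 if inside else 1.0)
    rows, cols = linear_sum_assignment(cost)
    seeded, ear_map = [], {}
    for i, c in zip(rows, cols):
        j, k = slots[c]
        ind = local_ids[j]
        ear_id = 2 * ind - 1 + k
        seeded.append(replace(observations[i], identity=ear_id))
        ear_map[ear_id] = ind
    return seeded, ear_map


def track_occlusion_fragment(seq, fragment: Fragment, detector, sim_model,
                             config: Config, flank_blobs: list[Blob] | None,
                             flank_ids: list[int] | None,
                             seed_frame: int | None, reverse: bool):
    """Ear tracking across one occlusion fragment, flanks included.

    Seeding happens on `seed_frame` (a flank): detections there are grouped
    to the identified blobs, fixing each individual's two ear identities.
    The fragment is then walked frame by frame (reversed when seeded on the
    after-flank), matching new detections to the last-seen observation of
    each ear identity with the similarity model.
    """
    frames = list(fragment.frames)
    if fragment.flank_before is not None:
        frames = [fragment.flank_before] + frames
    if fragment.flank_after is not None:
        frames = frames + [fragment.flank_after]
    if seed_frame is None:
        return {}
    if reverse:
        frames = frames[::-1]
    assert frames[0] == seed_frame
    obs0 = _observations_for_frame(seq, detector, seed_frame, config)
    seeded, ear_map = _seed_ears_from_blobs(obs0, flank_blobs or [],
                                            flank_ids or [])
    if not seeded:
        return {}
    pool: dict[int, EarObservation] = {o.identity: o for o in seeded}
    out: dict[int, dict[int, tuple[float, float]]] = {
        seed_frame: group_ears_to_individuals(seeded, ear_map)}
    for t in frames[1:]:
        detections = _observations_for_frame(seq, detector, t, config)
        assigned = []
        if detections:
            assigned = assign_identities(sim_model, list(pool.values()),
                                         detections,
                                         min_score=config.min_score)
            for o in assigned:
                if o.identity is not None:
                    pool[o.identity] = o
        out[t] = group_ears_to_individuals(
            [o for o in assigned if o.identity is not None], ear_map)
    return out


def track_video(seq: FrameSequence, detector, sim_model, config: Config):
    """Full tracking of a multi-subject video; returns everything the linker
    needs plus the preprocequences for audit."""
    blobs_per_frame, kinds, fragments, _ = preprocess_video(seq, config)
    blob_tracks: dict[int, list[BlobTrack]] = {}
    for k, frag in enumerate(fragments):
        if frag.kind == NON_OCCLUSION:
            blob_tracks[k] = track_fragment(frag, blobs_per_frame,
                                            width=seq.width)
    ear_tracks: dict[int, dict] = {}
    for k, frag in enumerate(fragments):
        if frag.kind != OCCLUSION:
            continue
        if frag.flank_before is not None:
            seed_frame, reverse, adj = frag.flank_before, False, k - 1
        elif frag.flank_after is not None:
            seed_frame, reverse, adj = frag.flank_after, True, k + 1
        else:
            get_logger().warning("occlusion fragment %d-%d has no flanks; "
                                 "left as gaps", frag.start, frag.end)
            continue
        tracks = blob_tracks.get(adj, [])
        blobs, ids = [], []
        for trk in tracks:
            if seed_frame in trk.blobs:
                blobs.append(trk.blobs[seed_frame])
                ids.append(trk.identity)
        ear_tracks[k] = track_occlusion_fragment(
            seq, frag, detector, sim_model, config,
            flank_blobs=blobs, flank_ids=ids,
            seed_frame=seed_frame, reverse=reverse)
    trajectories, report = link_fragments(fragments, blob_tracks, ear_tracks,
                                          config.n_subjects)
    return trajectories, report, fragments, blobs_per_frame, kinds


# ---------------------------------------------------------------------------
# stage: full run
# ---------------------------------------------------------------------------

def run_pipeline(config: Config, out_dir: str | Path,
                 detector=None, sim_model=None) -> PipelineRun:
    """Execute all stages; each stage's output is persisted under `out_dir`.

    Passing pre-trained models skips the training stage (a missing model
    with training implicitly enabled is trained on the spot).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = get_logger()
    run = PipelineRun(config=asdict(config), seed=config.seed)

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                run.timings[name] = time.perf_counter() - self.t0
                if exc[0] is not None:
                    log.error("stage %s failed", name)
                    return False
                log.info("stage %s done (%.1fs)", name, run.timings[name])
        return _T()

    with stage("simulate"):
        spec = arena_from_config(config)
        truth = write_dataset(spec, out_dir / "simulate")
        seq, _ = make_video(spec)
        run.artifacts["frames"] = str(out_dir / "simulate" / "frames")
        run.artifacts["truth_tracks"] = str(out_dir / "simulate" / "tracks.csv")

    with stage("train"):
        if detector is None or sim_model is None:
            detector, sim_model = train_models(config)
        save_model(detector, out_dir / "detector.npz")
        save_similarity_model(sim_model, out_dir / "siamese.npz")
        run.artifacts["detector"] = str(out_dir / "detector.npz")
        run.artifacts["siamese"] = str(out_dir / "siamese.npz")

    with stage("track"):
        trajectories, report, fragments, blobs_per_frame, kinds = \
            track_video(seq, detector, sim_model, config)
        pred_records = trajectories_to_records(trajectories)
        write_tracks(pred_records, out_dir / "tracks_pred.csv")
        write_linkage_report(report, out_dir / "linkage.json")
        with open(out_dir / "fragments.csv", "w") as fh:
            fh.write("kind,start,end,flank_before,flank_after\n")
            for f in fragments:
                fh.write(f"{f.kind},{f.start},{f.end},"
                         f"{f.flank_before},{f.flank_after}\n")
        run.artifacts["tracks_pred"] = str(out_dir / "tracks_pred.csv")
        run.artifacts["linkage"] = str(out_dir / "linkage.json")

    with stage("eval"):
        counts = score_tracks(pred_records, truth.track_records(),
                              match_radius=config.match_radius,
                              drift_radius=config.drift_radius,
                              mapping_window=config.mapping_window)
        run.metrics["icr"] = icr(counts)
        run.metrics["mota"] = mota(counts)
        eval_payload = {
            "counts": {k: int(v) for k, v in counts.__dict__.items()},
            "icr": run.metrics["icr"],
            "mota": run.metrics["mota"],
            "icr_percent": round(100 * run.metrics["icr"], 2),
            "mota_percent": round(100 * run.metrics["mota"], 2),
        }
        with open(out_dir / "eval.json", "w") as fh:
            json.dump(eval_payload, fh, indent=2)
        run.artifacts["eval"] = str(out_dir / "eval.json")

    with stage("behavior"):
        from .behavior import (RegionGrid, region_occupancy, spatial_sd,
                               velocity_series)
        grid = RegionGrid.for_arena(config.arena_width, config.arena_height)
        payload = {}
        for traj in trajectories:
            vel = velocity_series(traj, config.frame_rate, config.px_per_cm,
                                  config.block_seconds)
            pts = np.array([traj.positions[t] for t in sorted(traj.positions)])
            sd = spatial_sd(pts / config.px_per_cm)
            occ = region_occupancy(traj, grid)
            payload[f"subject_{traj.identity}"] = {
                "mean_speed": float(np.nanmean(vel.speeds)) if len(vel.speeds) else None,
                "block_means": [None if np.isnan(v) else float(v)
                                for v in vel.block_means],
                "sigma_2d": sd.sigma_2d,
                "region_fractions": [float(v) for v in occ.fractions],
                "n_gap_frames": len(traj.gap_frames()),
            }
        with open(out_dir / "behavior.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        run.artifacts["behavior"] = str(out_dir / "behavior.json")

    with open(out_dir / "run.json", "w") as fh:
        json.dump({"config": run.config, "seed": run.seed,
                   "artifacts": run.artifacts, "timings": run.timings,
                   "metrics": run.metrics}, fh, indent=2)
    return run
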