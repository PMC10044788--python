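import dataclasses

import numpy as np
import pytest

from eartrack.io_formats import Config
from eartrack.synthetic_arena import ArenaSpec, Paths, make_video, render_frames


def pipeline_config(**overrides) -> Config:
    """The desk-scale end-to-end study conditions (see docs/methods.md)."""
    cfg = Config(seed=1, n_subjects=2, frame_rate=40.0,
                 arena_width=128, arena_height=128,
                 body_major=11.0, body_minor=5.5, ear_radius=3.0,
                 speed_scale=2.5, n_frames=500, noise_sd=2.0,
                 train_video_frames=320, train_stride=8,
                 epochs=120, learning_rate=0.02, base_width=8,
                 confidence_threshold=0.4, match_radius=30.0,
                 drift_radius=11.0, min_score=0.2)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def pipeline_models():
    """Detector + similarity model trained once at the pipeline conditions."""
    from eartrack.pipeline import train_models
    return train_models(pipeline_config())


@pytest.fixture(scope="session")
def clean_spec2():
    """Small noise-free 2-subject arena used by several suites."""
    return ArenaSpec(width=160, height=160, n_subjects=2,
                     body_axes=(12.0, 6.0), ear_radius=2.5,
                     speed_scale=2.5, n_frames=250, frame_rate=40.0,
                     noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def clean_video2(clean_spec2):
    """Rendered frames + ground truth for the shared 2-subject arena."""
    return make_video(clean_spec2)


@pytest.fixture(scope="session")
def single_subject_video():
    """Noise-free single-subject clip for auto-labelling tests."""
    spec = ArenaSpec(width=160, height=160, n_subjects=1,
                     body_axes=(12.0, 6.0), ear_radius=2.5,
                     speed_scale=2.0, n_frames=60, frame_rate=40.0,
                     noise_sd=0.0, seed=11)
    seq, truth = make_video(spec)
    return spec, seq, truth


def disjoint_two_subject_video(n_frames=300, seed=3, width=320, height=160,
                               speed=2.5):
    """Two subjects confined to disjoint halves: guaranteed non-crossing.

    Each subject is simulated alone in a half-width arena; the second is then
    shifted into the right half.  Returns (spec, FrameSequence, GroundTruth).
    """
    half = ArenaSpec(width=width // 2, height=height, n_subjects=1,
                     body_axes=(12.0, 6.0), ear_radius=2.5,
                     speed_scale=speed, n_frames=n_frames, frame_rate=40.0,
                     noise_sd=0.0, seed=seed)
    from eartrack.synthetic_arena import simulate_trajectories
    a = simulate_trajectories(half)
    b = simulate_trajectories(ArenaSpec(**{**half.__dict__, "seed": seed + 1}))
    positions = np.concatenate([a.positions, b.positions], axis=1)
    positions[:, 1, 0] += width // 2
    headings = np.concatenate([a.headings, b.headings], axis=1)
    full = ArenaSpec(width=width, height=height, n_subjects=2,
                     body_axes=(12.0, 6.0), ear_radius=2.5,
                     speed_scale=speed, n_frames=n_frames, frame_rate=40.0,
                     noise_sd=0.0, seed=seed)
    seq, truth = render_frames(Paths(positions, headings, seed), full)
    return full, seq, truth
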