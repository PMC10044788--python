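"""Locomotion analytics on trajectories.

Covers the open-field measures used for group phenotyping: per-frame speed
and its means over 5-minute blocks, the two-dimensional standard deviation
of the spatial distribution

    sigma = sqrt( sum_i (x_i - xbar)^2 + (y_i - ybar)^2 / n )

(the population form, a scalar spread in length units), occupancy fractions
over a 12-region grid covering the central part of the arena, and the
Wilcoxon rank-sum test for group comparisons of non-normal variables.

Gap frames (where the tracker reports nothing) are excluded from every
statistic — positions are never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .io_formats import TrackRecord, ValidationError, get_logger
from .linker import Trajectory

__all__ = [
    "VelocitySeries",
    "SpatialStats",
    "RegionGrid",
    "RegionOccupancy",
    "velocity_series",
    "spatial_sd",
    "region_occupancy",
    "rank_sum_test",
    "records_to_trajectory",
]


@dataclass
class VelocitySeries:
    """Per-frame speeds (cm/s) and their 5-minute block means."""

    times: np.ndarray          # seconds, time of each speed sample
    speeds: np.ndarray         # cm/s
    block_means: np.ndarray    # mean speed per block (NaN where empty)
    block_seconds: float
    px_per_cm: float
    frame_rate: float


@dataclass
class SpatialStats:
    """Mean position and the 2-D population standard deviation."""

    mean_x: float
    mean_y: float
    sigma_2d: float
    n: int


@dataclass(frozen=True)
class RegionGrid:
    """The central-region grid: 160x160 cells over x 320-960, y 240-720.

    Region ids run 1..12 row-major (left to right, then top to bottom) by
    default; `numbering` may override with an explicit permutation of 1..n.
    """

    x_min: float = 320.0
    x_max: float = 960.0
    y_min: float = 240.0
    y_max: float = 720.0
    cell: float = 160.0
    numbering: tuple[int, ...] | None = None

    def __post_init__(self):
        for lo, hi in ((self.x_min, self.x_max), (self.y_min, self.y_max)):
            span = hi - lo
            if span <= 0 or abs(span / self.cell - round(span / self.cell)) > 1e-9:
                raise ValidationError("grid extent must be a positive multiple "
                                      "of the cell size")
        if self.numbering is not None and sorted(self.numbering) != list(
                range(1, self.n_regions + 1)):
            raise ValidationError("numbering must be a permutation of 1..n")

    @classmethod
    def for_arena(cls, width: float, height: float) -> "RegionGrid":
        """The canonical 4x3 central grid scaled to an arbitrary arena:
        columns span the central half of the width; rows form a centred
        band three cells tall."""
        cell = width / 8.0
        y_mid = height / 2.0
        return cls(x_min=width / 4.0, x_max=3 * width / 4.0,
                   y_min=y_mid - 1.5 * cell, y_max=y_mid + 1.5 * cell,
                   cell=cell)

    @property
    def n_cols(self) -> int:
        return round((self.x_max - self.x_min) / self.cell)

    @property
    def n_rows(self) -> int:
        return round((self.y_max - self.y_min) / self.cell)

    @property
    def n_regions(self) -> int:
        return self.n_cols * self.n_rows

    def region_of(self, x: float, y: float) -> int | None:
        """1-based region id, or None when outside the main region."""
        if not (self.x_min <= x < self.x_max and self.y_min <= y < self.y_max):
            return None
        col = int((x - self.x_min) // self.cell)
        row = int((y - self.y_min) // self.cell)
        idx = row * self.n_cols + col
        return self.numbering[idx] if self.numbering else idx + 1


@dataclass
class RegionOccupancy:
    grid: RegionGrid
    fractions: np.ndarray      # indexed by region id - 1
    n_frames: int              # total frames considered (in and out of region)


def records_to_trajectory(records: list[TrackRecord], identity: int) -> Trajectory:
    traj = Trajectory(identity=identity)
    for r in records:
        if r.identity == identity:
            traj.positions[r.frame_index] = (r.x, r.y)
            traj.sources[r.frame_index] = "blob"
    return traj


def velocity_series(traj: Trajectory, frame_rate: float, px_per_cm: float,
                    block_seconds: float = 300.0) -> VelocitySeries:
    """Speed between consecutive tracked frames, and 5-minute block means.

    Speed at step t is the Euclidean displacement times the frame rate over
    the pixel calibration; steps that span a gap are excluded from both the
    series and the block means.  The number of blocks is
    ceil(duration / block_seconds) over the full trajectory span.
    """
    if px_per_cm <= 0 or frame_rate <= 0:
        raise ValidationError("px_per_cm and frame_rate must be positive")
    frames = sorted(traj.positions)
    if len(frames) < 2:
        raise ValidationError("velocity needs at least two tracked positions")
    times, speeds = [], []
    for a, b in zip(frames, frames[1:]):
        if b - a != 1:
            continue  # spans a gap
        (x0, y0), (x1, y1) = traj.positions[a], traj.positions[b]
        speeds.append(math.hypot(x1 - x0, y1 - y0) * frame_rate / px_per_cm)
        times.append(a / frame_rate)
    times = np.asarray(times)
    speeds = np.asarray(speeds)
    duration = (frames[-1] - frames[0] + 1) / frame_rate
    n_blocks = max(1, math.ceil(duration / block_seconds))
    block_means = np.full(n_blocks, np.nan)
    start = frames[0] / frame_rate
    for b in range(n_blocks):
        sel = (times >= start + b * block_seconds) & \
              (times < start + (b + 1) * block_seconds)
        if sel.any():
            block_means[b] = speeds[sel].mean()
    return VelocitySeries(times=times, speeds=speeds, block_means=block_means,
                          block_seconds=block_seconds, px_per_cm=px_per_cm,
                          frame_rate=frame_rate)


def spatial_sd(points) -> SpatialStats:
    """Two-dimensional population standard deviation of positions (in the
    units of the input, conventionally cm)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValidationError("spatial_sd needs at least one point")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    mean = pts.mean(axis=0)
    sigma = math.sqrt(float(((pts - mean) ** 2).sum() / len(pts)))
    return SpatialStats(mean_x=float(mean[0]), mean_y=float(mean[1]),
                        sigma_2d=sigma, n=len(pts))


def region_occupancy(traj: Trajectory, grid: RegionGrid | None = None) -> RegionOccupancy:
    """Fraction of tracked frames spent in each grid region.

    Fractions are counts divided by the total number of tracked frames, so
    they sum to at most 1 (frames outside the main region are excluded from
    the numerators but kept in the denominator).
    """
    grid = grid or RegionGrid()
    counts = np.zeros(grid.n_regions)
    total = 0
    for t in sorted(traj.positions):
        x, y = traj.positions[t]
        total += 1
        region = grid.region_of(x, y)
        if region is not None:
            counts[region - 1] += 1
    if total == 0:
        raise ValidationError("empty trajectory")
    return RegionOccupancy(grid=grid, fractions=counts / total, n_frames=total)


def rank_sum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties; otherwise the normal approximation with
    tie correction.  Fully tied data degenerate to p = 1 (logged).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        get_logger().info("rank_sum_test: all values tied; p = 1.0")
        return 1.0
    ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
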