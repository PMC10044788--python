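"""Axis-aligned boxes and overlap arithmetic.

Boxes are half-open pixel rectangles [x_min, x_max) x [y_min, y_max) in a
coordinate frame with the origin at the top-left corner, x rightward and
y downward.  The half-open convention makes areas and intersections exact
integer arithmetic for pixel-aligned boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BBox", "iou", "iou_matrix"]


@dataclass(frozen=True)
class BBox:
    """Half-open axis-aligned bounding box in pixels."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def clip(self, width: float, height: float) -> "BBox":
        """Clip to an image of the given size; raises if nothing remains."""
        return BBox(
            min(max(self.x_min, 0.0), width - 1e-9),
            min(max(self.y_min, 0.0), height - 1e-9),
            max(min(self.x_max, float(width)), max(self.x_min, 0.0) + 1e-9),
            max(min(self.y_max, float(height)), max(self.y_min, 0.0) + 1e-9),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(boxes_a: list[BBox], boxes_b: list[BBox]) -> np.ndarray:
    """Pairwise IoU, shape (len(a), len(b)); vectorised."""
    if not boxes_a or not boxes_b:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a = np.stack([b.as_array() for b in boxes_a])
    b = np.stack([bb.as_array() for bb in boxes_b])
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)
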