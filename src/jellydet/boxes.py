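"""Axis-aligned bounding boxes.

One convention everywhere: 0-based pixel coordinates, ``(x_min, y_min,
x_max, y_max)``, half-open (``x_max``/``y_max`` exclusive), so
``width = x_max - x_min`` with no off-by-one terms.  The Pascal-VOC
readers/writers in :mod:`jellydet.annotations` translate to and from
VOC's 1-based inclusive dialect at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

#: Class-id -> name mapping for the eight-way label space: seven jellyfish
#: species plus fish as a disruptor class.
CLASS_NAMES: tuple[str, ...] = (
    "c_purpurea",
    "r_pulmo",
    "p_camtschatica",
    "a_okeni",
    "a_aurita",
    "p_punctata",
    "r_esculentum",
    "fish",
)

NUM_CLASSES = len(CLASS_NAMES)


@dataclass(frozen=True)
class DetectionBox:
    """A labelled box; ``confidence`` is ``None`` for ground truth."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")

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
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clip(self, width: float, height: float) -> Optional["DetectionBox"]:
        """Intersect with the ``[0,width) x [0,height)`` canvas.

        Returns ``None`` when nothing remains.
        """
        x0 = max(self.x_min, 0.0)
        y0 = max(self.y_min, 0.0)
        x1 = min(self.x_max, float(width))
        y1 = min(self.y_max, float(height))
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection-over-union of two boxes under the half-open convention."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0
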