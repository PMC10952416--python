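"""Geometry of the two-compartment "2-box" apparatus.

The box is two congruent rectangular compartments sharing the wall that
contains the doorway.  In box coordinates compartment 1 spans
``x in [0, W)`` and compartment 2 spans ``x in [W, 2W)``; both span
``y in [0, H)``.  A cue card sits on the far short end of each compartment
(notionally north for compartment 1 and south for compartment 2), so the two
local visual layouts are 180-degree reversals of each other.  Each compartment
carries one odor (lemon or vanilla).

All coordinates are centimetres; the origin is the box's lower-left (south-
west) corner, x rightward, y upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ODORS = ("vanilla", "lemon")


@dataclass(frozen=True)
class BoxGeometry:
    """Dimensions, doorway and odor layout of the 2-box.

    Parameters
    ----------
    compartment_width, compartment_height
        Inner size of one compartment, cm.  The full box is
        ``2 * compartment_width`` by ``compartment_height``.
    door_width
        Width of the doorway opening, centred on the shared wall, cm.
    odor_assignment
        Mapping ``{compartment index (1 or 2): odor name}``.
    """

    compartment_width: float = 60.0
    compartment_height: float = 90.0
    door_width: float = 20.0
    odor_assignment: dict = field(
        default_factory=lambda: {1: "vanilla", 2: "lemon"}
    )

    def __post_init__(self):
        if self.compartment_width <= 0 or self.compartment_height <= 0:
            raise ValueError("compartment dimensions must be positive")
        if not 0 < self.door_width < self.compartment_height:
            raise ValueError("door_width must lie in (0, compartment_height)")
        if set(self.odor_assignment) != {1, 2} or set(
            self.odor_assignment.values()
        ) != set(ODORS):
            raise ValueError(
                "odor_assignment must map compartments {1, 2} onto "
                f"{set(ODORS)}"
            )

    # -- derived extents ---------------------------------------------------
    @property
    def width(self) -> float:
        """Full box width (both compartments), cm."""
        return 2.0 * self.compartment_width

    @property
    def height(self) -> float:
        return self.compartment_height

    @property
    def door_span(self) -> tuple[float, float]:
        """(y_lo, y_hi) of the doorway opening on the shared wall."""
        c = self.compartment_height / 2.0
        return (c - self.door_width / 2.0, c + self.door_width / 2.0)

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.width / 2.0, self.height / 2.0])

    def compartment_bounds(self, comp: int) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, y_lo, y_hi) of compartment 1 or 2."""
        if comp == 1:
            return (0.0, self.compartment_width, 0.0, self.height)
        if comp == 2:
            return (self.compartment_width, self.width, 0.0, self.height)
        raise ValueError("compartment must be 1 or 2")

    def compartment_of(self, x) -> np.ndarray:
        """Compartment index per sample; doorway samples go to the nearest
        compartment centroid, which reduces to thresholding x at the wall."""
        return np.where(np.asarray(x) < self.compartment_width, 1, 2)

    def compartment_for_odor(self, odor: str) -> int:
        for comp, o in self.odor_assignment.items():
            if o == odor:
                return comp
        raise KeyError(odor)

    # -- frame transforms --------------------------------------------------
    def rotate180(self, p: np.ndarray) -> np.ndarray:
        """180-degree rotation of box-frame points about the box centre."""
        p = np.asarray(p, dtype=float)
        return np.array([self.width, self.height]) - p

    def to_local(self, p, comp: int) -> np.ndarray:
        """Box-frame point -> compartment-local frame (origin at the
        compartment's own lower-left corner, axes unchanged)."""
        x_lo, _, _, _ = self.compartment_bounds(comp)
        return np.asarray(p, dtype=float) - np.array([x_lo, 0.0])

    def to_global(self, p_local, comp: int) -> np.ndarray:
        x_lo, _, _, _ = self.compartment_bounds(comp)
        return np.asarray(p_local, dtype=float) + np.array([x_lo, 0.0])

    def local_rot180(self, p_local) -> np.ndarray:
        """180-degree rotation within one compartment (about its centre)."""
        return np.array(
            [self.compartment_width, self.compartment_height]
        ) - np.asarray(p_local, dtype=float)

    def scene_position(self, p_local, comp: int) -> np.ndarray:
        """Compartment-local point -> visual-scene frame (cue card 'up').

        Compartment 1's scene frame coincides with its local frame; compartment
        2's layout is reversed, so its scene frame is the 180-degree rotation.
        """
        p_local = np.asarray(p_local, dtype=float)
        return p_local if comp == 1 else self.local_rot180(p_local)


def rotate_point(p, angle_deg: int, width: float, height: float) -> np.ndarray:
    """Rotate box-frame points into a room frame rotated by ``angle_deg``
    (multiples of 90, counter-clockwise) about the box footprint.

    The returned coordinates are relative to the rotated footprint's own
    lower-left corner, so they stay non-negative.
    """
    p = np.asarray(p, dtype=float)
    x, y = p[..., 0], p[..., 1]
    k = (angle_deg // 90) % 4
    if k == 0:
        out = p
    elif k == 1:  # (x, y) -> (-y, x), shifted into [0, H) x [0, W)
        out = np.stack([height - y, x], axis=-1)
    elif k == 2:
        out = np.stack([width - x, height - y], axis=-1)
    else:
        out = np.stack([y, width - x], axis=-1)
    return out


def rotated_extent(angle_deg: int, width: float, height: float) -> tuple[float, float]:
    """Footprint (width, height) after rotating by ``angle_deg``."""
    if (angle_deg // 90) % 2 == 1:
        return (height, width)
    return (width, height)
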