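"""Task conditions and hemisphere/arm bookkeeping.

The task has 8 unimanual conditions: performing arm (left/right) x cycling
direction (forward/backward) x starting pedal position (top/bottom).  For a
neuron, the *driven* arm is the arm contralateral to its hemisphere; for a
muscle, the arm it acts on.  The *driving cortex* for a condition is the
hemisphere contralateral to the performing arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

ARMS = ("left", "right")
DIRECTIONS = ("forward", "backward")
STARTS = ("top", "bottom")
HEMISPHERES = ("left", "right")


@dataclass(frozen=True, order=True)
class Condition:
    """One performing-arm x direction x start-position combination."""

    arm: str
    direction: str
    start: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.start not in STARTS:
            raise ValueError(f"start must be one of {STARTS}, got {self.start!r}")

    @property
    def label(self) -> str:
        return f"{self.arm}-{self.direction}-{self.start}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        arm, direction, start = label.split("-")
        return cls(arm, direction, start)

    def with_other_arm(self) -> "Condition":
        return Condition(other_arm(self.arm), self.direction, self.start)

    def with_other_start(self) -> "Condition":
        other = "bottom" if self.start == "top" else "top"
        return Condition(self.arm, self.direction, other)


#: All 8 unimanual conditions in a fixed canonical order.
ALL_CONDITIONS = tuple(
    Condition(a, d, s) for a, d, s in product(ARMS, DIRECTIONS, STARTS)
)


def other_arm(arm: str) -> str:
    return "right" if arm == "left" else "left"


def driven_arm(hemisphere: str) -> str:
    """Arm contralateral to a hemisphere (the arm its output drives)."""
    return other_arm(hemisphere)


def driving_hemisphere(arm: str) -> str:
    """Hemisphere contralateral to (driving) the given arm."""
    return other_arm(arm)


def conditions_for_arm(arm: str):
    """The four conditions performed with `arm`, in canonical order."""
    return tuple(c for c in ALL_CONDITIONS if c.arm == arm)


def conditions_for_start(start: str):
    """The four conditions starting at `start`, in canonical order."""
    return tuple(c for c in ALL_CONDITIONS if c.start == start)
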