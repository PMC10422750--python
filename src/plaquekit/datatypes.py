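"""Core data containers.

The imaging side of the package works on 8-bit RGB intraoral photographs
taken under ultraviolet light after a sodium-fluorescein staining rinse.
Plaque shows up in the green/blue channel balance of each pixel, so the
containers here keep the raw channel grids together with the per-pixel
plaque category and the per-subject clinical indices derived from them.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Mapping

import numpy as np

__all__ = [
    "PlaqueClass",
    "UVPhotograph",
    "PlaqueLabelMap",
    "PlaqueIndexSet",
    "SubjectTimeline",
    "VIEWS",
    "DAYS",
]

#: The three standard intraoral views captured per subject per visit.
VIEWS = ("frontal", "left", "right")

#: Visit days of the two-phase design (phase 1: days 0-4, phase 2: days 4-8).
DAYS = (0, 4, 8)


class PlaqueClass(enum.IntEnum):
    """Per-pixel plaque category.

    ``VISIBLE`` is mature plaque (green channel exceeds blue);
    ``NON_VISIBLE`` is immature plaque (green above the post-cleaning
    reference but not above blue, with the two channels close);
    ``CLEAN_TOOTH`` is plaque-free enamel; ``BACKGROUND`` is everything
    outside the tooth mask.
    """

    BACKGROUND = 0
    CLEAN_TOOTH = 1
    VISIBLE = 2
    NON_VISIBLE = 3


#: Classes that count as plaque when computing area percentages.
PLAQUE_CLASSES = frozenset({PlaqueClass.VISIBLE, PlaqueClass.NON_VISIBLE})


@dataclasses.dataclass
class UVPhotograph:
    """An 8-bit RGB intraoral photograph taken under UV light.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, channel order R, G, B.
    subject_id, day, view
        Capture metadata. ``day`` is the visit day (0, 4 or 8) and
        ``view`` one of :data:`VIEWS`.
    """

    pixels: np.ndarray
    subject_id: str = "anon"
    day: int = 0
    view: str = "frontal"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def green(self) -> np.ndarray:
        """Green channel as int16 (safe for signed channel arithmetic)."""
        return self.pixels[..., 1].astype(np.int16)

    @property
    def blue(self) -> np.ndarray:
        """Blue channel as int16."""
        return self.pixels[..., 2].astype(np.int16)


@dataclasses.dataclass
class PlaqueLabelMap:
    """Per-pixel plaque categories for one photograph.

    ``labels`` is an ``(H, W)`` integer grid over :class:`PlaqueClass`.
    By contract, ``BACKGROUND`` appears exactly where the tooth mask is
    false, and the three tooth classes partition the mask.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        valid = {int(c) for c in PlaqueClass}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label values: {sorted(present - valid)}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def tooth_mask(self) -> np.ndarray:
        return self.labels != PlaqueClass.BACKGROUND

    def class_count(self, cls: PlaqueClass) -> int:
        return int(np.count_nonzero(self.labels == cls))

    def tooth_pixel_count(self) -> int:
        return int(np.count_nonzero(self.labels != PlaqueClass.BACKGROUND))

    def class_fractions(self) -> dict[PlaqueClass, float]:
        """Fraction of *tooth* pixels in each tooth class."""
        n = self.tooth_pixel_count()
        if n == 0:
            raise ValueError("label map has no tooth pixels")
        return {
            cls: self.class_count(cls) / n
            for cls in (PlaqueClass.CLEAN_TOOTH, PlaqueClass.VISIBLE, PlaqueClass.NON_VISIBLE)
        }


@dataclasses.dataclass
class PlaqueIndexSet:
    """The clinical indices for one subject at one timepoint.

    Areas are percentages of the pooled tooth surface; growth rates are
    cumulative area divided by the hours elapsed since the day-0
    professional cleaning (% area/hour). The *relative* visible area
    subtracts the subject's own post-cleaning baseline (clamped at 0);
    growth rates at hour 0 are undefined and stored as NaN.
    """

    visible_area_abs: float
    visible_area_rel: float
    nonvisible_area: float
    total_area: float
    visible_growth_abs: float
    visible_growth_rel: float
    total_growth: float
    elapsed_hours: float

    def __post_init__(self) -> None:
        for name in ("visible_area_abs", "visible_area_rel", "nonvisible_area", "total_area"):
            v = getattr(self, name)
            # tolerate float round-off from I/O round-trips, then snap
            if not -1e-6 <= v <= 100.0 + 1e-6:
                raise ValueError(f"{name}={v} outside [0, 100]")
            setattr(self, name, min(max(v, 0.0), 100.0))
        if self.elapsed_hours < 0:
            raise ValueError("elapsed_hours must be >= 0")
        if not math.isclose(
            self.total_area,
            self.visible_area_abs + self.nonvisible_area,
            abs_tol=1e-6,
        ):
            raise ValueError("total_area must equal visible_area_abs + nonvisible_area")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SubjectTimeline:
    """One subject's group assignment and indices at 0/96/192 hours."""

    subject_id: str
    group: str
    records: Mapping[float, PlaqueIndexSet]

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError(f"group must be 'A' or 'B', got {self.group!r}")
        self.records = dict(sorted(self.records.items()))
        if 0 not in self.records:
            raise ValueError("timeline must contain the hour-0 (post-cleaning) record")

    @property
    def hours(self) -> tuple[float, ...]:
        return tuple(self.records)

    @property
    def baseline(self) -> PlaqueIndexSet:
        return self.records[0]
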