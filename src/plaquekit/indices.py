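"""Clinical plaque indices derived from label maps.

Two index families are computed for visible, non-visible and total
(visible + non-visible) plaque:

* **Plaque area** — percentage of the tooth surface covered by plaque.
  The *absolute* variant is computed on the analysed image alone; the
  *relative* variant subtracts the same subject's area right after the
  day-0 professional cleaning (clamped at zero), so it measures plaque
  accrued since the cleaning.
* **Plaque growth** — area percentage divided by the hours elapsed since
  the cleaning (% area/hour). Growth is cumulative from hour 0, not
  incremental between visits.

All three intraoral views of a subject (frontal + two lateral) are
pooled *before* percentages are taken: one denominator counting every
tooth pixel across views.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .datatypes import PLAQUE_CLASSES, PlaqueClass, PlaqueIndexSet, PlaqueLabelMap

__all__ = [
    "area_percent",
    "relative_area_percent",
    "growth_rate",
    "pool_views",
    "index_set_from_labels",
]


def area_percent(
    labels: PlaqueLabelMap,
    plaque_classes: Iterable[PlaqueClass] = PLAQUE_CLASSES,
) -> float:
    """Percentage of tooth pixels carrying the given plaque classes.

    ``plaque_classes`` is a subset of {VISIBLE, NON_VISIBLE}; passing
    both yields the total-plaque area.
    """
    classes = set(plaque_classes)
    if not classes <= PLAQUE_CLASSES:
        raise ValueError(f"plaque_classes must be a subset of {PLAQUE_CLASSES}")
    n_tooth = labels.tooth_pixel_count()
    if n_tooth == 0:
        raise ValueError("empty tooth mask: area percentage is undefined")
    n_plaque = sum(labels.class_count(c) for c in classes)
    return 100.0 * n_plaque / n_tooth


def relative_area_percent(current_abs: float, baseline_abs: float) -> float:
    """Relative plaque area: absolute area minus the subject's own day-0
    (post-cleaning) baseline, clamped at zero.
    """
    for name, v in (("current_abs", current_abs), ("baseline_abs", baseline_abs)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return max(current_abs - baseline_abs, 0.0)


def growth_rate(area: float, elapsed_hours: float) -> float:
    """Plaque growth: cumulative area (%) per hour since the cleaning."""
    if elapsed_hours <= 0:
        raise ValueError("elapsed_hours must be > 0 (growth undefined at hour 0)")
    return area / elapsed_hours


def pool_views(view_label_maps: Sequence[PlaqueLabelMap]) -> PlaqueLabelMap:
    """Pool the label maps of several views into one flat label map.

    Pixel counts are what matter downstream, so pooling simply
    concatenates all pixels into a single-row label map; every area
    percentage computed on it uses the combined tooth-pixel denominator.
    """
    if len(view_label_maps) == 0:
        raise ValueError("need at least one view")
    flat = np.concatenate([m.labels.ravel() for m in view_label_maps])
    return PlaqueLabelMap(flat[np.newaxis, :])


def index_set_from_labels(
    view_label_maps: Sequence[PlaqueLabelMap],
    baseline_visible_abs: float,
    elapsed_hours: float,
) -> PlaqueIndexSet:
    """Compute the full per-visit index set from one visit's label maps.

    ``baseline_visible_abs`` is the subject's pooled visible area at the
    day-0 cleaning. At ``elapsed_hours == 0`` the growth rates are NaN.
    """
    pooled = pool_views(view_label_maps)
    visible = area_percent(pooled, {PlaqueClass.VISIBLE})
    nonvisible = area_percent(pooled, {PlaqueClass.NON_VISIBLE})
    return build_index_set(visible, nonvisible, baseline_visible_abs, elapsed_hours)


def build_index_set(
    visible_abs: float,
    nonvisible: float,
    baseline_visible_abs: float,
    elapsed_hours: float,
) -> PlaqueIndexSet:
    """Assemble a :class:`PlaqueIndexSet` from area components.

    The relative index uses the visible-area baseline; total plaque is
    visible + non-visible of the same visit. A non-visible *relative*
    area is deliberately not produced (it has no defined baseline
    semantics in this index family).
    """
    visible_rel = relative_area_percent(visible_abs, baseline_visible_abs)
    total = visible_abs + nonvisible
    if elapsed_hours > 0:
        g_abs = growth_rate(visible_abs, elapsed_hours)
        g_rel = growth_rate(visible_rel, elapsed_hours)
        g_tot = growth_rate(total, elapsed_hours)
    else:
        g_abs = g_rel = g_tot = math.nan
    return PlaqueIndexSet(
        visible_area_abs=visible_abs,
        visible_area_rel=visible_rel,
        nonvisible_area=nonvisible,
        total_area=total,
        visible_growth_abs=g_abs,
        visible_growth_rel=g_rel,
        total_growth=g_tot,
        elapsed_hours=elapsed_hours,
    )
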