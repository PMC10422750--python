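"""Per-pixel plaque classification from UV photographs.

Fluorescein-stained plaque shifts the green/blue balance of a pixel.
Mature ("visible") plaque fluoresces strongly enough that the green
channel exceeds the blue channel outright. Immature ("non-visible")
plaque is detected relatively: its green value rises above the green
value the same pixel had right after professional cleaning (the
registered day-0 reference), while remaining at or below the blue value
— but close to it. Clean enamel stays strongly blue-dominant.

The rule, per tooth pixel with green ``G``, blue ``B`` and day-0
reference green ``G_ref``::

    visible      iff  G > B
    non_visible  iff  not visible  and  G > G_ref + eps  and  B - G <= tau
    clean_tooth  otherwise

with ``tau`` the closeness margin quantifying "close" and ``eps`` an
optional noise guard on the reference comparison. Pixels outside the
tooth mask are background. Tooth masks are an input: automatic tooth
detection is out of scope here.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datatypes import PlaqueClass, PlaqueLabelMap, UVPhotograph

__all__ = ["ClassifierConfig", "classify_pixels", "classification_accuracy"]


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the channel rule.

    closeness_margin
        ``tau``, in 8-bit intensity units: the largest blue-minus-green
        excess still counted as "close" for the non-visible class. The
        default (30) keeps the non-visible band more than two noise
        standard deviations away from both class boundaries for
        per-channel noise SD up to ~7.
    reference_delta
        ``eps``, in 8-bit units: minimum excess over the reference green
        required to count as plaque at all. Default 0 (strict reading of
        the definition); raise it to absorb sensor noise.
    """

    closeness_margin: float = 30.0
    reference_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.closeness_margin < 0:
            raise ValueError("closeness_margin must be >= 0")
        if self.reference_delta < 0:
            raise ValueError("reference_delta must be >= 0")


def _green_blue(image: UVPhotograph | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(image, UVPhotograph):
        return image.green, image.blue
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    return arr[..., 1].astype(np.int16), arr[..., 2].astype(np.int16)


def classify_pixels(
    image: UVPhotograph | np.ndarray,
    mask: np.ndarray,
    reference: UVPhotograph | np.ndarray,
    config: ClassifierConfig | None = None,
) -> PlaqueLabelMap:
    """Classify every pixel of a UV photograph into plaque categories.

    Parameters
    ----------
    image
        The photograph to analyse.
    mask
        Boolean tooth mask of the same height/width; pixels outside it
        are labelled background.
    reference
        The registered day-0 capture of the same view (taken right after
        professional cleaning); only its green channel is used.
    config
        Thresholds; defaults to :class:`ClassifierConfig`.

    Returns
    -------
    PlaqueLabelMap
        Visible / non-visible / clean-tooth labels on the mask,
        background outside it.

    Raises
    ------
    ValueError
        If image, mask and reference dimensions disagree (unregistered
        inputs), or the reference is missing.
    """
    if reference is None:
        raise ValueError("missing reference: the registered day-0 image is required")
    if config is None:
        config = ClassifierConfig()
    g, b = _green_blue(image)
    g_ref, _ = _green_blue(reference)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != g.shape or g_ref.shape != g.shape:
        raise ValueError(
            f"dimension mismatch: image {g.shape}, mask {mask.shape}, "
            f"reference {g_ref.shape} — inputs must be registered"
        )

    visible = g > b
    non_visible = (
        ~visible
        & (g > g_ref + config.reference_delta)
        & (b - g <= config.closeness_margin)
    )

    labels = np.full(g.shape, int(PlaqueClass.CLEAN_TOOTH), dtype=np.uint8)
    labels[visible] = int(PlaqueClass.VISIBLE)
    labels[non_visible] = int(PlaqueClass.NON_VISIBLE)
    labels[~mask] = int(PlaqueClass.BACKGROUND)
    return PlaqueLabelMap(labels)


def classification_accuracy(
    predicted: PlaqueLabelMap, truth: PlaqueLabelMap
) -> dict[str, float | dict[str, float]]:
    """Pixel agreement between a predicted label map and ground truth.

    Returns a dict with ``"overall"`` (fraction of all pixels agreeing)
    and ``"per_class"`` mapping each class name to the fraction of that
    class's *truth* pixels predicted identically (NaN for classes absent
    from the truth).
    """
    p, t = predicted.labels, truth.labels
    if p.shape != t.shape:
        raise ValueError(f"dimension mismatch: predicted {p.shape} vs truth {t.shape}")
    agree = p == t
    per_class: dict[str, float] = {}
    for cls in PlaqueClass:
        sel = t == cls
        n = int(sel.sum())
        per_class[cls.name.lower()] = float(agree[sel].mean()) if n else float("nan")
    return {"overall": float(agree.mean()), "per_class": per_class}
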