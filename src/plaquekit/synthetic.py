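"""Synthetic UV scenes with exact ground truth, and simulated trials.

Real inputs to this pipeline are intraoral photographs under UV light
plus subject-level timelines from a two-group, two-phase mouthwash
trial. Neither is publicly deposited, so this module generates both:

* :func:`render_scene` draws a row of ellipse "teeth" over a dark
  background with a gingiva band, carves visible / non-visible plaque
  regions out of a smoothed random field (mimicking patchy cervical
  accumulation), and paints each class with fixed channel levels chosen
  to satisfy the classifier inequalities by construction. It returns the
  image, a perfectly registered day-0 reference (same geometry, clean
  channel levels), the tooth mask and the exact label map.

* :func:`simulate_trial` draws per-subject timelines for the 2-group ×
  3-visit design (days 0/4/8 = 0/96/192 h): a near-zero post-cleaning
  baseline, then linear-in-time visible-plaque accumulation with
  phase- and group-specific growth rates. Group A receives the active
  (cymenol) rinse in both phases; group B receives placebo in phase 1
  and the active rinse in phase 2. Default rates are calibrated so the
  group means match the reference trial's printed visible-area means.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse

from . import indices
from .datatypes import PlaqueClass, PlaqueLabelMap, SubjectTimeline, UVPhotograph

__all__ = [
    "SceneSpec",
    "GroundTruthScene",
    "render_scene",
    "TrialSimSpec",
    "simulate_trial",
]

# Fixture channel levels (8-bit). Arbitrary constants chosen so every
# classifier inequality holds with >= 2 noise SDs of margin at noise
# SD 5 per channel (difference SD ~7.1): visible G-B = +60; non-visible
# B-G = 15, centred in the (0, tau=30] closeness band and 40 above the
# reference green; clean B-G = 50 > tau.
DEFAULT_CHANNEL_LEVELS: dict[str, float] = {
    "clean_g": 60.0,
    "clean_b": 110.0,
    "visible_g": 150.0,
    "visible_b": 90.0,
    "nonvisible_g": 95.0,
    "nonvisible_b": 110.0,
    "reference_g": 55.0,
}

_BACKGROUND_RGB = (8, 12, 25)
_GINGIVA_RGB = (120, 35, 55)
_TOOTH_R = 60.0  # red channel is ignored by the classifier


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic UV scene.

    ``target_visible_fraction`` / ``target_nonvisible_fraction`` are the
    desired proportions of tooth pixels per plaque class;
    ``channel_levels`` the mean 8-bit G/B values per class (keys as in
    :data:`DEFAULT_CHANNEL_LEVELS`); ``channel_noise_sd`` the per-channel
    Gaussian noise SD; ``closeness_margin`` the tau the classifier is
    expected to use on this scene.
    """

    image_height: int = 120
    image_width: int = 180
    n_teeth: int = 6
    tooth_axis_rows: tuple[float, float] = (28.0, 38.0)
    tooth_axis_cols: tuple[float, float] = (11.0, 15.0)
    target_visible_fraction: float = 0.2
    target_nonvisible_fraction: float = 0.15
    channel_levels: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_LEVELS)
    )
    channel_noise_sd: float = 0.0
    closeness_margin: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1 or self.n_teeth < 1:
            raise ValueError("image dimensions and n_teeth must be positive")
        fv, fn = self.target_visible_fraction, self.target_nonvisible_fraction
        if not (0 <= fv <= 1 and 0 <= fn <= 1 and fv + fn <= 1):
            raise ValueError("plaque fractions must lie in [0, 1] and sum to <= 1")
        if self.channel_noise_sd < 0:
            raise ValueError("channel_noise_sd must be >= 0")
        lv = self.channel_levels
        missing = set(DEFAULT_CHANNEL_LEVELS) - set(lv)
        if missing:
            raise ValueError(f"channel_levels missing keys: {sorted(missing)}")
        # The levels must be classifiable by construction; otherwise the
        # scene's ground truth would be unrecoverable even without noise.
        tau = self.closeness_margin
        problems = []
        if not lv["visible_g"] > lv["visible_b"]:
            problems.append("visible requires G > B")
        if not lv["nonvisible_g"] <= lv["nonvisible_b"]:
            problems.append("non-visible requires G <= B")
        if not lv["nonvisible_b"] - lv["nonvisible_g"] <= tau:
            problems.append("non-visible requires B - G <= closeness_margin")
        if not lv["nonvisible_g"] > lv["reference_g"]:
            problems.append("non-visible requires G > reference G")
        if not lv["clean_b"] - lv["clean_g"] > tau:
            problems.append("clean requires B - G > closeness_margin")
        if problems:
            raise ValueError("unclassifiable channel levels: " + "; ".join(problems))


@dataclasses.dataclass
class GroundTruthScene:
    """A rendered scene bundled with its exact ground truth."""

    image: UVPhotograph
    reference_image: UVPhotograph
    tooth_mask: np.ndarray
    truth_labels: PlaqueLabelMap
    spec: SceneSpec


def _tooth_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Row of slightly jittered, possibly overlapping ellipses."""
    mask = np.zeros((spec.image_height, spec.image_width), dtype=bool)
    centres = np.linspace(0, spec.image_width, spec.n_teeth + 2)[1:-1]
    row_c = spec.image_height * 0.58
    for c in centres:
        ax_r = rng.uniform(*spec.tooth_axis_rows) / 2
        ax_c = rng.uniform(*spec.tooth_axis_cols)
        jit_r = rng.uniform(-3, 3)
        jit_c = rng.uniform(-2, 2)
        rr, cc = ellipse(
            row_c + jit_r, c + jit_c, ax_r, ax_c, shape=mask.shape
        )
        mask[rr, cc] = True
    return mask


def _plaque_partition(
    spec: SceneSpec, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign tooth pixels to classes via a smoothed random field.

    The field is Gaussian-smoothed white noise plus a downward row
    gradient, so high values cluster in patchy blobs biased toward the
    cervical (lower) tooth margin. The top ``target_visible_fraction``
    quantile becomes visible plaque, the next ``target_nonvisible``
    slice non-visible; exact pixel counts make the achieved fractions
    match the targets to within one pixel.
    """
    labels = np.full(mask.shape, int(PlaqueClass.BACKGROUND), dtype=np.uint8)
    labels[mask] = int(PlaqueClass.CLEAN_TOOTH)
    n_tooth = int(mask.sum())
    n_vis = round(spec.target_visible_fraction * n_tooth)
    n_non = round(spec.target_nonvisible_fraction * n_tooth)
    if n_vis + n_non == 0:
        return labels
    field = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=5.0)
    field += np.linspace(-0.5, 0.5, mask.shape[0])[:, np.newaxis]
    order = np.argsort(field[mask])[::-1]  # tooth pixels, highest field first
    tooth_idx = np.flatnonzero(mask.ravel())
    flat = labels.ravel()
    flat[tooth_idx[order[:n_vis]]] = int(PlaqueClass.VISIBLE)
    flat[tooth_idx[order[n_vis : n_vis + n_non]]] = int(PlaqueClass.NON_VISIBLE)
    return flat.reshape(mask.shape)


def _paint(
    labels: np.ndarray,
    mask: np.ndarray,
    g_levels: Mapping[int, float],
    b_levels: Mapping[int, float],
    noise_sd: float,
    rng: np.random.Generator,
    gingiva_rows: slice,
) -> np.ndarray:
    h, w = labels.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = _BACKGROUND_RGB
    img[gingiva_rows, :, :] = _GINGIVA_RGB
    img[mask, 0] = _TOOTH_R
    for cls, g in g_levels.items():
        sel = labels == cls
        img[sel, 1] = g
        img[sel, 2] = b_levels[cls]
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_scene(spec: SceneSpec) -> GroundTruthScene:
    """Render a synthetic UV scene with exact ground-truth labels.

    Deterministic for a fixed ``spec.seed``. The reference image shares
    the scene's geometry exactly (perfect registration — the capture
    device standardises positioning) with every tooth pixel painted at
    the clean/reference levels.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _tooth_mask(spec, rng)
    labels = _plaque_partition(spec, mask, rng)
    lv = spec.channel_levels

    gingiva_rows = slice(0, int(spec.image_height * 0.22))
    g_levels = {
        int(PlaqueClass.CLEAN_TOOTH): lv["clean_g"],
        int(PlaqueClass.VISIBLE): lv["visible_g"],
        int(PlaqueClass.NON_VISIBLE): lv["nonvisible_g"],
    }
    b_levels = {
        int(PlaqueClass.CLEAN_TOOTH): lv["clean_b"],
        int(PlaqueClass.VISIBLE): lv["visible_b"],
        int(PlaqueClass.NON_VISIBLE): lv["nonvisible_b"],
    }
    pixels = _paint(labels, mask, g_levels, b_levels, spec.channel_noise_sd, rng, gingiva_rows)

    ref_g = {cls: lv["reference_g"] for cls in g_levels}
    ref_b = {cls: lv["clean_b"] for cls in b_levels}
    ref_pixels = _paint(
        labels, mask, ref_g, ref_b, spec.channel_noise_sd, rng, gingiva_rows
    )

    return GroundTruthScene(
        image=UVPhotograph(pixels),
        reference_image=UVPhotograph(ref_pixels, day=0),
        tooth_mask=mask,
        truth_labels=PlaqueLabelMap(labels),
        spec=spec,
    )


# --- trial simulation -------------------------------------------------------

# Visible-area growth-rate means (% area/hour) per (group, phase),
# calibrated so group mean areas at 96 h and 192 h land on the reference
# trial's printed visible-area means given the printed group baselines:
# e.g. group A phase 1: (35.31 - 5.57) / 96. Group B's phase-1 rate is
# the placebo rate; its phase-2 rate reflects switching to the active
# rinse. SDs for phase 1 come from variance differencing of the printed
# area SDs; phase-2 SDs are small (see docs/methods.md).
DEFAULT_GROWTH_RATE_MEANS: dict[tuple[str, int], float] = {
    ("A", 1): (35.31 - 5.57) / 96.0,
    ("A", 2): (44.79 - 35.31) / 96.0,
    ("B", 1): (46.57 - 5.68) / 96.0,
    ("B", 2): (65.12 - 46.57) / 96.0,
}
DEFAULT_GROWTH_RATE_SDS: dict[tuple[str, int], float] = {
    ("A", 1): 0.151,
    ("A", 2): 0.053,
    ("B", 1): 0.194,
    ("B", 2): 0.055,
}


@dataclasses.dataclass
class TrialSimSpec:
    """Parameters of the simulated two-group, two-phase trial.

    Defaults reproduce the reference trial's structure: 24 subjects in
    group A (active rinse both phases), 26 in group B (placebo then
    active), a near-zero post-cleaning baseline (mean 5.6%, SD 3.5%),
    visits at 0/96/192 h, and growth rates per (group, phase) calibrated
    to the printed group means. All areas are clamped to [0, 100] and
    rate draws truncated at 0.
    """

    n_group_a: int = 24
    n_group_b: int = 26
    baseline_area_mean: float = 5.6
    baseline_area_sd: float = 3.5
    growth_rate_means: Mapping[tuple[str, int], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROWTH_RATE_MEANS)
    )
    growth_rate_sds: Mapping[tuple[str, int], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROWTH_RATE_SDS)
    )
    nonvisible_area_mean: float = 26.8
    nonvisible_area_sd: float = 10.8
    timepoints_hours: tuple[float, float, float] = (0.0, 96.0, 192.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need n >= 2 per group for any downstream statistics")
        t = self.timepoints_hours
        if len(t) != 3 or t[0] != 0 or not (t[0] < t[1] < t[2]):
            raise ValueError("timepoints must be (0, t1, t2) strictly increasing")
        keys = {(g, p) for g in "AB" for p in (1, 2)}
        if set(self.growth_rate_means) != keys or set(self.growth_rate_sds) != keys:
            raise ValueError("growth rates must cover (group, phase) for A/B x 1/2")
        if any(v < 0 for v in self.growth_rate_means.values()):
            raise ValueError("growth-rate means must be >= 0")


def _truncate(draws: np.ndarray, lo: float, hi: float | None = None) -> np.ndarray:
    return np.clip(draws, lo, hi)


def simulate_trial(spec: TrialSimSpec) -> list[SubjectTimeline]:
    """Simulate per-subject index timelines for the two-phase design.

    Per subject: baseline visible area ~ N(mean, sd) truncated to
    [0, 100]; the area at the end of each phase adds (phase rate draw x
    phase hours), clamped to [0, 100]; non-visible area is drawn per
    post-baseline visit (0 at the cleaning visit); every index is then
    computed through :mod:`plaquekit.indices`. Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    t0, t1, t2 = spec.timepoints_hours
    timelines: list[SubjectTimeline] = []
    counter = 0
    for group, n in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        baselines = _truncate(
            rng.normal(spec.baseline_area_mean, spec.baseline_area_sd, size=n), 0, 100
        )
        r1 = _truncate(
            rng.normal(
                spec.growth_rate_means[(group, 1)],
                spec.growth_rate_sds[(group, 1)],
                size=n,
            ),
            0,
        )
        r2 = _truncate(
            rng.normal(
                spec.growth_rate_means[(group, 2)],
                spec.growth_rate_sds[(group, 2)],
                size=n,
            ),
            0,
        )
        nonvis = _truncate(
            rng.normal(
                spec.nonvisible_area_mean, spec.nonvisible_area_sd, size=(n, 2)
            ),
            0,
            100,
        )
        for i in range(n):
            counter += 1
            base = float(baselines[i])
            area_t1 = float(np.clip(base + r1[i] * (t1 - t0), 0, 100))
            area_t2 = float(np.clip(area_t1 + r2[i] * (t2 - t1), 0, 100))
            records = {}
            for hours, vis, nv in (
                (t0, base, 0.0),
                (t1, area_t1, float(nonvis[i, 0])),
                (t2, area_t2, float(nonvis[i, 1])),
            ):
                nv = min(nv, 100.0 - vis)  # keep total within [0, 100]
                records[hours] = indices.build_index_set(
                    visible_abs=vis,
                    nonvisible=nv,
                    baseline_visible_abs=base,
                    elapsed_hours=hours,
                )
            timelines.append(
                SubjectTimeline(
                    subject_id=f"S{counter:03d}", group=group, records=records
                )
            )
    return timelines
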