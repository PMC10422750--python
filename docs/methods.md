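# Methods

## Pixel classification

The classifier operates on registered 8-bit RGB photographs of
fluorescein-stained dentition under UV light. Per tooth pixel, with
green `G`, blue `B` and day-0 reference green `G_ref`:

| label | condition |
|---|---|
| visible | `G > B` |
| non_visible | not visible and `G > G_ref + eps` and `B - G <= tau` |
| clean_tooth | otherwise |
| background | outside the tooth mask |

Ties break conservatively: `G == B` is not visible and `G == G_ref` is
not non-visible (strict inequalities). The red channel is ignored.
Assumptions: the reference image is the pixelwise-registered day-0
capture of the same view (the capture device standardises head and
camera positioning, so perfect registration is assumed), and tooth
masks are supplied by the caller — automatic tooth detection is out of
scope.

**Closeness margin `tau`.** The non-visible definition requires green
"close to" blue without quantifying closeness. We read it as a fixed
margin `B - G <= tau`, configurable, default `tau = 30` (8-bit units).
The default comes from a noise budget rather than any empirical claim:
with independent per-channel Gaussian noise of SD `s`, the `B - G`
difference has SD `s*sqrt(2)` (~7.1 at `s = 5`). Placing the synthetic
non-visible band at `B - G = 15`, i.e. centred in `(0, tau]`, leaves
~2.1 difference-SDs to both the visible boundary (`B - G = 0`) and the
clean boundary (`B - G = tau`), so per-pixel misclassification stays
below ~2% per side at `s = 5`. A margin of 15 with the band at
`B - G = 5` — a configuration we initially considered — leaves only
0.7 SD to the visible boundary and misclassifies ~30% of non-visible
pixels at the same noise level, which is why the wider default was
adopted. `eps` (default 0) is a strict reading of the reference
comparison; raising it trades non-visible sensitivity for robustness to
reference noise.

## Clinical indices

All three views of a visit are pooled *before* percentages are taken
(single denominator over all tooth pixels), so larger views weigh more,
matching a whole-dentition reading.

- `area = 100 * plaque_pixels / tooth_pixels` (%); total plaque uses
  visible + non-visible, which makes `total = visible + nonvisible`
  exact by construction of the label partition.
- `relative = max(area - baseline_area, 0)`: the published relative
  means are consistent with "absolute minus same-subject day-0
  baseline" to within 0.4 area-% in every available cell, so that
  subtraction (clamped at zero) is the adopted definition.
- `growth = area / elapsed_hours`, *cumulative* from the cleaning, not
  per-interval: the published day-8 rates equal area/192 to two
  decimals in all six cells, which fixes this reading. Visit clocks are
  idealised to exactly 96 h (day 4) and 192 h (day 8); the source
  design gives only day counts.
- A non-visible *relative* area has no defined baseline semantics and
  is not produced.

Growth is undefined (NaN) at hour 0; `area_percent` raises on an empty
tooth mask rather than returning a silent 0/0.

## Synthetic scenes

`render_scene` is the testing ground truth for the classifier: teeth
are overlapping ellipses on a dark background with a gingiva band;
plaque regions are carved from Gaussian-smoothed white noise plus a
vertical gradient (patchy blobs biased toward the cervical margin);
per-class pixel counts are taken by exact quantile selection, so
achieved fractions match targets to within a pixel. Channel levels are
fixture constants — clean (G=60, B=110), visible (G=150, B=90),
non-visible (G=95, B=110), reference G=55 — chosen to satisfy every
classifier inequality with the noise margins described above; they are
not claims about real fluorescence spectra. What the renderer does
*not* emulate: specular highlights, exposure variation, saliva film,
interdental shadows, registration error, or camera noise beyond
i.i.d. Gaussian per-channel noise. Pixel-perfect recovery on noise-free
scenes therefore demonstrates internal consistency of the rule and the
pipeline plumbing, not clinical segmentation accuracy.

## Trial simulator

The simulator reproduces the *statistical structure* of a 50-subject,
two-phase trial: group A (n=24) uses the active rinse in both 4-day
phases; group B (n=26) placebo then active. Per subject: baseline
visible area ~ N(5.6, 3.5²) truncated to [0, 100] (near-zero plaque
after professional cleaning), then linear-in-time accumulation
`area(t+96) = area(t) + 96 * r` with phase- and group-specific rates
`r ~ N(mu, sd²)` truncated at 0. Linear growth follows from the
cumulative-growth index: a constant rate is the simplest process whose
area/elapsed-hours statistic is stable across visits.

Rate means are calibrated so group mean areas land on the published
visible-area means given the published baselines, e.g.
`mu(A, phase1) = (35.31 - 5.57)/96 ≈ 0.310 %/h`. Phase-1 rate SDs come
from variance differencing of the published area SDs
(`sqrt(14.93² - 3.57²)/96 ≈ 0.151` for A, 0.194 for B); the group-A
phase-2 SD likewise (≈0.053). Group B's published day-8 area SD is
*smaller* than its day-4 SD, so differencing under independence gives a
negative variance; its phase-2 SD is set to 0.055, mirroring group A.
Non-visible area is drawn i.i.d. per post-baseline visit from
N(26.8, 10.8²) — the only published non-visible means — and capped so
total ≤ 100. The published totals are slightly inconsistent with
visible + non-visible additivity (57.49 vs 35.31 + 27.69 at the day-4
group-A cell); the simulator keeps additivity exact, so simulated
totals run a few points above the published totals. Consequences: the
simulated phase-1 visible-growth reduction converges to ~24% (the value
implied by unrounded calibrated means), while the published 26% was
computed from unrounded subject-level data that is not recoverable from
printed tables.

One other published-count note: the source reports 504 images in one
place and 450 (50 subjects × 3 days × 3 views) in another; the
simulator follows the 450 accounting.

## Statistical pipeline

- **Normality gate**: Shapiro–Wilk at α = 0.05 on *each* group (or on
  the within-subject differences for paired contrasts); the parametric
  branch requires both groups to pass. Constant samples count as
  non-normal (Shapiro is undefined there).
- **Independent branch**: Student's t with pooled variance, two-sided.
  Nonparametric: Mann–Whitney U, two-sided; exact when both n < 12 and
  there are no ties, otherwise the normal approximation with tie and
  continuity corrections.
- **Paired branch**: with only two timepoints per contrast, the
  parametric repeated-measures branch reduces to a paired t run as the
  Bonferroni post-hoc (the source names no specific post-hoc test; this
  is our interpretation, flagged in the report note). Nonparametric:
  Wilcoxon signed-rank. All-zero differences are reported as p = 1 with
  a degeneracy note rather than an error.
- **Bonferroni**: three pairwise timepoint contrasts give an internal
  threshold of 0.05/3 ≈ 0.0167; reports display the conventional 0.016
  while the significance flag uses the exact internal value.
- **Percent reduction**: `round(100 * (1 - r_test/r_ref))`, half away
  from zero; scale-invariant; undefined for a non-positive reference
  rate.
- **Sample size**: smallest integer per-group n whose noncentral-t
  power for a two-sided two-sample t-test at effect size d reaches the
  target (statsmodels `TTestIndPower`); at d = 0.80, α = 0.05, power
  0.80 this yields 26 per group. Tests cross-check the result against a
  brute-force Monte-Carlo power oracle.

`build_trial_tables` assembles: between-group contrasts at every visit
(baseline visible area at hour 0; six indices at days 4 and 8),
within-group day-4 vs day-8 contrasts for seven indices per group, and
reduction percentages in three families — phase-1 active vs placebo,
end-of-trial rates vs the group-B phase-1 placebo rate, and
within-group phase-2 vs phase-1.

## Problem sizes and numerical choices

Simulation-backed checks use problem sizes chosen for stable estimates:
1000 replicates at the trial's own group sizes (24/26) for type-I
calibration (binomial SE ≈ 0.7 points at a 5% level), 500
subjects/group for mean-recovery and effect-detection checks (SE of a
group mean area ≈ 0.7 area-%), 50 scenes per noise condition for
classifier agreement. Scene images default to 120×180 px with 6 teeth —
small enough to render in milliseconds, large enough for ±2-point
fraction targeting. All randomness flows through
`numpy.random.default_rng` seeds carried in the spec objects; fixed
seeds give bit-identical scenes, timelines and CLI manifests.

## Limitations

- The synthetic calibration reproduces published group means/SDs under
  normality and truncation; real subject-level distributions (skew,
  within-subject correlation across phases) are unknown, so simulated
  p-values cannot and do not reproduce the source's subject-level
  p-values — only directions, effect recovery and error calibration are
  checked.
- Between-phase rate draws are independent within subject; if real
  growth rates are strongly correlated within subject, paired-contrast
  variances here are conservative.
- The classifier is a faithful implementation of a published *rule*,
  not a re-validation of it; no claim is made about its accuracy on
  real photographs.
- Sphericity and multiplicity handling beyond the Bonferroni-over-3
  scheme are out of scope, as are covariate adjustment and equivalence
  testing.
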