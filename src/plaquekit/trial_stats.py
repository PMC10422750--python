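"""Trial statistics: normality-gated comparisons, power, reductions.

The analysis plan mirrors a two-group, two-phase mouthwash trial:

* **Independent contrasts** (group A vs group B at each visit): both
  samples are screened with Shapiro–Wilk at alpha = 0.05; if both pass,
  Student's t for independent samples (pooled variance), otherwise the
  Mann–Whitney U. Significance at p < 0.05.
* **Paired contrasts** (within a group, visit vs visit): normality of
  the within-subject differences gates a repeated-measures-style
  parametric branch (the two-timepoint contrast is a paired t run as the
  Bonferroni post-hoc) versus the Wilcoxon signed-rank test. With three
  pairwise timepoint comparisons the Bonferroni threshold is 0.05/3,
  conventionally displayed as 0.016.
* **Fisher's exact** for 2x2 categorical balance (e.g. gender by group).
* **Percent reduction** of a growth rate versus a reference rate,
  rounded to the nearest integer percent (half away from zero).
* **A-priori sample size** for a two-sided two-sample t-test from
  effect size d, alpha and power, via the noncentral-t power function.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from .datatypes import SubjectTimeline

__all__ = [
    "ComparisonReport",
    "PowerSpec",
    "TrialReport",
    "select_and_run_independent",
    "select_and_run_paired",
    "fisher_balance",
    "percent_reduction",
    "sample_size_two_groups",
    "build_trial_tables",
]

SHAPIRO_ALPHA = 0.05
INDEPENDENT_THRESHOLD = 0.05
#: Internal Bonferroni threshold for three pairwise timepoint contrasts.
BONFERRONI_THRESHOLD = 0.05 / 3
#: The conventional two-decimal display of 0.05/3.
BONFERRONI_DISPLAY = 0.016


@dataclasses.dataclass
class ComparisonReport:
    """One row of a results table: a single statistical contrast."""

    index_name: str
    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    n: tuple[int, int]
    test_used: str  # student_t | mann_whitney | rm_anova | wilcoxon | fisher_exact
    p_value: float
    significance_threshold: float
    significant: bool
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["labels"] = list(self.labels)
        d["means"] = list(self.means)
        d["sds"] = list(self.sds)
        d["n"] = list(self.n)
        return d


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """A-priori power computation for two independent groups."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size d must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


def _is_normal(x: np.ndarray) -> bool:
    """Shapiro–Wilk gate; constant samples count as non-normal."""
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > SHAPIRO_ALPHA


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1))


def select_and_run_independent(
    values_a: Sequence[float],
    values_b: Sequence[float],
    index_name: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonReport:
    """Normality-gated two-group comparison (Student's t or Mann–Whitney U).

    Both groups must pass Shapiro–Wilk at alpha 0.05 for the pooled
    two-sided t-test; otherwise the two-sided Mann–Whitney U is used
    (exact when both n < 12 and there are no ties, else the
    tie-corrected normal approximation with continuity correction).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    note = ""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        note = "degenerate: zero variance in both groups"
        if a[0] == b[0]:
            p, test = 1.0, "mann_whitney"
        else:
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
            test = "mann_whitney"
    elif _is_normal(a) and _is_normal(b):
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        test = "student_t"
    else:
        no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        method = "exact" if (a.size < 12 and b.size < 12 and no_ties) else "asymptotic"
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
        test = "mann_whitney"
    ma, sa = _mean_sd(a)
    mb, sb = _mean_sd(b)
    return ComparisonReport(
        index_name=index_name,
        labels=labels,
        means=(ma, mb),
        sds=(sa, sb),
        n=(a.size, b.size),
        test_used=test,
        p_value=p,
        significance_threshold=INDEPENDENT_THRESHOLD,
        significant=p < INDEPENDENT_THRESHOLD,
        note=note,
    )


def select_and_run_paired(
    values_t1: Sequence[float],
    values_t2: Sequence[float],
    paired_ids: Sequence | None = None,
    index_name: str = "",
    labels: tuple[str, str] = ("t1", "t2"),
) -> ComparisonReport:
    """Normality-gated paired comparison with Bonferroni threshold.

    The within-subject differences are screened with Shapiro–Wilk: if
    normal, the parametric repeated-measures branch applies (for a
    two-timepoint contrast this is the paired t as Bonferroni post-hoc,
    reported as ``rm_anova``); otherwise the Wilcoxon signed-rank test.
    Significance at the Bonferroni-corrected 0.05/3 (displayed 0.016).
    """
    t1 = np.asarray(values_t1, dtype=float)
    t2 = np.asarray(values_t2, dtype=float)
    if t1.size != t2.size:
        raise ValueError("paired samples must have equal length")
    if paired_ids is not None:
        ids = list(paired_ids)
        if len(ids) != t1.size:
            raise ValueError("paired_ids length must match the samples")
        if len(set(ids)) != len(ids):
            raise ValueError("unmatched ids: subject ids must be unique")
    if t1.size < 3:
        raise ValueError("need n >= 3 pairs")
    diffs = t2 - t1
    note = ""
    if np.all(diffs == 0):
        p, test = 1.0, "wilcoxon"
        note = "degenerate: all within-subject differences are zero"
    elif _is_normal(diffs):
        p = float(stats.ttest_rel(t1, t2).pvalue)
        test = "rm_anova"
        note = "paired t as Bonferroni post-hoc of the repeated-measures branch"
    else:
        p = float(stats.wilcoxon(t1, t2).pvalue)
        test = "wilcoxon"
    m1, s1 = _mean_sd(t1)
    m2, s2 = _mean_sd(t2)
    return ComparisonReport(
        index_name=index_name,
        labels=labels,
        means=(m1, m2),
        sds=(s1, s2),
        n=(t1.size, t2.size),
        test_used=test,
        p_value=p,
        significance_threshold=BONFERRONI_DISPLAY,
        significant=p < BONFERRONI_THRESHOLD,
        note=note,
    )


def fisher_balance(
    counts_2x2: Sequence[Sequence[int]],
    index_name: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonReport:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    table = np.asarray(counts_2x2)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty margin: every row and column needs a count")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    col_tot = table.sum(axis=0)
    return ComparisonReport(
        index_name=index_name,
        labels=labels,
        means=(float(table[0, 0]), float(table[0, 1])),
        sds=(0.0, 0.0),
        n=(int(col_tot[0]), int(col_tot[1])),
        test_used="fisher_exact",
        p_value=p,
        significance_threshold=INDEPENDENT_THRESHOLD,
        significant=p < INDEPENDENT_THRESHOLD,
        note="means fields hold the first-row counts",
    )


def percent_reduction(rate_test: float, rate_reference: float) -> int:
    """Reduction of a growth rate vs a reference, as an integer percent.

    ``100 * (1 - rate_test / rate_reference)`` rounded to the nearest
    integer, half away from zero. Scale-invariant in the two rates.
    """
    if rate_reference <= 0:
        raise ValueError("rate_reference must be > 0")
    value = 100.0 * (1.0 - rate_test / rate_reference)
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def sample_size_two_groups(spec: PowerSpec) -> int:
    """Smallest per-group n reaching the target power for a two-sided
    two-sample t-test at effect size d (noncentral-t power function,
    equal allocation).
    """
    solver = TTestIndPower()
    n = 2
    while n < 1_000_000:
        achieved = solver.power(
            effect_size=spec.effect_size,
            nobs1=n,
            alpha=spec.alpha,
            ratio=1.0,
            alternative="two-sided",
        )
        if achieved >= spec.power:
            return n
        n += 1
    raise ValueError("target power unreachable")


# --- full trial tables ------------------------------------------------------

_INDEX_FIELDS = (
    ("visible_area_abs", "Visible plaque area (absolute)"),
    ("visible_area_rel", "Visible plaque area (relative)"),
    ("nonvisible_area", "Non-visible plaque area"),
    ("total_area", "Total plaque area"),
    ("visible_growth_abs", "Visible plaque area growth (absolute)"),
    ("visible_growth_rel", "Visible plaque area growth (relative)"),
    ("total_growth", "Total plaque area growth"),
)
_FIELD_TITLES = dict(_INDEX_FIELDS)


@dataclasses.dataclass
class TrialReport:
    """All contrasts and reduction percentages of one simulated trial.

    ``independent`` mirrors the group-A-vs-B table at each visit,
    ``paired_a`` / ``paired_b`` the within-group end-of-phase-1 vs
    end-of-phase-2 tables, and ``reductions`` the growth-rate reduction
    percentages derived from group mean rates.
    """

    independent: list[ComparisonReport]
    paired_a: list[ComparisonReport]
    paired_b: list[ComparisonReport]
    reductions: dict[str, int]
    group_sizes: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "independent": [r.as_dict() for r in self.independent],
            "paired_a": [r.as_dict() for r in self.paired_a],
            "paired_b": [r.as_dict() for r in self.paired_b],
            "reductions": dict(self.reductions),
            "group_sizes": dict(self.group_sizes),
        }


def timelines_to_frame(timelines: Sequence[SubjectTimeline]) -> pd.DataFrame:
    """Long-format view of timelines: one row per subject x visit."""
    rows = []
    for tl in timelines:
        for hours, rec in tl.records.items():
            row = {"subject_id": tl.subject_id, "group": tl.group, "hours": hours}
            row.update(rec.as_dict())
            row.pop("elapsed_hours")
            rows.append(row)
    return pd.DataFrame(rows)


def _visit_values(
    frame: pd.DataFrame, group: str, hours: float, field: str
) -> pd.Series:
    sel = frame[(frame["group"] == group) & (frame["hours"] == hours)]
    return sel.sort_values("subject_id").set_index("subject_id")[field]


def build_trial_tables(timelines: Sequence[SubjectTimeline]) -> TrialReport:
    """Run the full between- and within-group analysis on timelines.

    Emits the independent A-vs-B contrasts at every visit (baseline
    visible area at hour 0; all indices at the later visits), the paired
    end-of-phase contrasts within each group, and the growth-rate
    reduction percentages: phase-1 active-vs-placebo, within-group
    phase-2-vs-phase-1, and end-of-trial rates against the group-B
    phase-1 placebo rate.
    """
    frame = timelines_to_frame(timelines)
    hours = sorted(frame["hours"].unique())
    if len(hours) != 3:
        raise ValueError("expected exactly three visit timepoints")
    t0, t1, t2 = hours
    counts = frame.groupby("group")["subject_id"].nunique()
    for g in ("A", "B"):
        if g not in counts:
            raise ValueError(f"group {g} missing from timelines")
        expect = counts[g] * 3
        if (frame["group"] == g).sum() != expect:
            raise ValueError(f"group {g} has subjects with missing timepoints")

    independent: list[ComparisonReport] = []
    for hrs, fields in (
        (t0, ("visible_area_abs",)),
        (t1, [f for f, _ in _INDEX_FIELDS if f != "nonvisible_area"]),
        (t2, [f for f, _ in _INDEX_FIELDS if f != "nonvisible_area"]),
    ):
        for field in fields:
            a = _visit_values(frame, "A", hrs, field)
            b = _visit_values(frame, "B", hrs, field)
            independent.append(
                select_and_run_independent(
                    a,
                    b,
                    index_name=f"{_FIELD_TITLES[field]} @ {hrs:g} h",
                    labels=("A", "B"),
                )
            )

    paired = {}
    for group in ("A", "B"):
        reports = []
        for field, title in _INDEX_FIELDS:
            v1 = _visit_values(frame, group, t1, field)
            v2 = _visit_values(frame, group, t2, field)
            reports.append(
                select_and_run_paired(
                    v1.values,
                    v2.values,
                    paired_ids=v1.index,
                    index_name=f"{title}, group {group}",
                    labels=(f"{t1:g} h", f"{t2:g} h"),
                )
            )
        paired[group] = reports

    mean_rate = {
        (g, h, f): float(_visit_values(frame, g, h, f).mean())
        for g in ("A", "B")
        for h in (t1, t2)
        for f in ("visible_growth_abs", "visible_growth_rel", "total_growth")
    }
    placebo = {f: mean_rate[("B", t1, f)] for f in
               ("visible_growth_abs", "visible_growth_rel", "total_growth")}
    reductions = {
        # phase 1: active (A) vs placebo (B) at the day-4 visit
        "phase1_visible_abs_A_vs_B": percent_reduction(
            mean_rate[("A", t1, "visible_growth_abs")], placebo["visible_growth_abs"]
        ),
        "phase1_visible_rel_A_vs_B": percent_reduction(
            mean_rate[("A", t1, "visible_growth_rel")], placebo["visible_growth_rel"]
        ),
        # end of trial vs the phase-1 placebo rate
        "day8_visible_abs_A_vs_placebo": percent_reduction(
            mean_rate[("A", t2, "visible_growth_abs")], placebo["visible_growth_abs"]
        ),
        "day8_visible_abs_B_vs_placebo": percent_reduction(
            mean_rate[("B", t2, "visible_growth_abs")], placebo["visible_growth_abs"]
        ),
        "day8_total_A_vs_placebo": percent_reduction(
            mean_rate[("A", t2, "total_growth")], placebo["total_growth"]
        ),
        "day8_total_B_vs_placebo": percent_reduction(
            mean_rate[("B", t2, "total_growth")], placebo["total_growth"]
        ),
        # within-group: end of phase 2 vs end of phase 1
        "within_A_visible_abs": percent_reduction(
            mean_rate[("A", t2, "visible_growth_abs")],
            mean_rate[("A", t1, "visible_growth_abs")],
        ),
        "within_A_visible_rel": percent_reduction(
            mean_rate[("A", t2, "visible_growth_rel")],
            mean_rate[("A", t1, "visible_growth_rel")],
        ),
        "within_A_total": percent_reduction(
            mean_rate[("A", t2, "total_growth")], mean_rate[("A", t1, "total_growth")]
        ),
        "within_B_visible_abs": percent_reduction(
            mean_rate[("B", t2, "visible_growth_abs")],
            mean_rate[("B", t1, "visible_growth_abs")],
        ),
        "within_B_visible_rel": percent_reduction(
            mean_rate[("B", t2, "visible_growth_rel")],
            mean_rate[("B", t1, "visible_growth_rel")],
        ),
        "within_B_total": percent_reduction(
            mean_rate[("B", t2, "total_growth")], mean_rate[("B", t1, "total_growth")]
        ),
    }

    return TrialReport(
        independent=independent,
        paired_a=paired["A"],
        paired_b=paired["B"],
        reductions=reductions,
        group_sizes={g: int(counts[g]) for g in ("A", "B")},
    )


def reports_to_frame(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    """Tabular rendering of contrast reports (one row each)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "index": r.index_name,
                f"mean_{r.labels[0]}": r.means[0],
                f"sd_{r.labels[0]}": r.sds[0],
                f"mean_{r.labels[1]}": r.means[1],
                f"sd_{r.labels[1]}": r.sds[1],
                "test": r.test_used,
                "p_value": r.p_value,
                "threshold": r.significance_threshold,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def render_markdown(report: TrialReport) -> str:
    """Human-readable Markdown rendering of a :class:`TrialReport`."""
    out = ["# Trial analysis report", ""]
    out.append(
        f"Group sizes: A = {report.group_sizes['A']}, B = {report.group_sizes['B']}"
    )
    for title, reports in (
        ("Independent contrasts (group A vs group B)", report.independent),
        ("Paired contrasts, group A (end of phase 1 vs phase 2)", report.paired_a),
        ("Paired contrasts, group B (end of phase 1 vs phase 2)", report.paired_b),
    ):
        out += ["", f"## {title}", ""]
        out.append("| index | mean ± SD (1) | mean ± SD (2) | test | p | sig |")
        out.append("|---|---|---|---|---|---|")
        for r in reports:
            out.append(
                f"| {r.index_name} | {r.means[0]:.2f} ± {r.sds[0]:.2f} "
                f"| {r.means[1]:.2f} ± {r.sds[1]:.2f} | {r.test_used} "
                f"| {r.p_value:.4g} | {'*' if r.significant else ''} |"
            )
    out += ["", "## Growth-rate reductions (%)", ""]
    for k, v in report.reductions.items():
        out.append(f"- {k}: {v}%")
    return "\n".join(out) + "\n"
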