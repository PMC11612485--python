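"""Cohort statistics for per-area reporter densities.

Per-image densities are averaged to one value per biological subject
(images nest within subjects; subjects are the replication unit). Groups
are compared by one-way ANOVA with Bonferroni-corrected pairwise pooled-
variance t tests, or a two-group unpaired two-tailed t test. Helpers
compute fold changes, percent-of-youngest standardization and the
box-plot five-number summary.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SIGNIFICANCE_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                       (0.05, "*"))


def stars(p: float) -> str:
    for thr, sym in SIGNIFICANCE_LEVELS:
        if p < thr:
            return sym
    return "ns"


def aggregate_subjects(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    group_col: str = "group",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Collapse per-image rows to per-subject means.

    Every image row must carry a subject and group; the subject value of
    each measure is the mean over that subject's images.
    """
    if table[subject_col].isna().any():
        raise ValueError("orphan images: rows with no subject")
    if table[group_col].isna().any():
        raise ValueError("orphan images: rows with no group")
    multi = table.groupby(subject_col)[group_col].nunique()
    if (multi > 1).any():
        bad = multi[multi > 1].index.tolist()
        raise ValueError(f"subjects mapped to multiple groups: {bad}")
    if measures is None:
        measures = [
            c for c in table.columns
            if c not in (group_col, subject_col)
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    out = (
        table.groupby([group_col, subject_col], sort=False)[measures]
        .mean()
        .reset_index()
    )
    return out


def t_test_two_tailed(a, b) -> tuple[float, int, float]:
    """Unpaired two-tailed Student t test with pooled variance.

    Returns (t, df, p). Degenerate zero-variance input follows the
    conventions: equal means -> t=0, p=1; unequal means -> infinite t, p=0
    (with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return float(np.sign(diff)) * np.inf, df, 0.0
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


@dataclass
class AnovaResult:
    """Omnibus one-way ANOVA plus Bonferroni-corrected pairwise tests."""

    F: float
    p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # group_a, group_b, t, df, p_raw, p_adj, stars


def one_way_anova_bonferroni(
    table: pd.DataFrame,
    measure: str,
    comparisons: list[tuple[str, str]] | None = None,
    group_col: str = "group",
) -> AnovaResult:
    """One-way ANOVA across groups with Bonferroni post hoc correction.

    Pairwise comparisons are pooled-variance t tests between the requested
    group pairs (all pairs by default); adjusted p = min(1, p_raw x m) with
    m the number of comparisons performed.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = {g: table.loc[table[group_col] == g, measure].to_numpy(float)
               for g in groups}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    F, p = sps.f_oneway(*samples.values())
    n = sum(v.size for v in samples.values())
    if comparisons is None:
        comparisons = list(itertools.combinations(groups, 2))
    m = len(comparisons)
    rows = []
    for ga, gb in comparisons:
        if ga not in samples or gb not in samples:
            raise ValueError(f"comparison ({ga!r}, {gb!r}) names unknown group")
        t, df, p_raw = t_test_two_tailed(samples[ga], samples[gb])
        p_adj = min(1.0, p_raw * m)
        rows.append((ga, gb, t, df, p_raw, p_adj, stars(p_adj)))
    pairwise = pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "t", "df", "p_raw", "p_adj", "stars"],
    )
    return AnovaResult(
        F=float(F), p=float(p), df_between=len(groups) - 1,
        df_within=n - len(groups), pairwise=pairwise,
    )


def percent_of_youngest(
    table: pd.DataFrame,
    measure: str,
    youngest_group: str = "young",
    group_col: str = "group",
) -> pd.DataFrame:
    """Standardize a measure as percent of the youngest group's mean.

    The youngest group's mean maps to exactly 100; the transform is a
    positive rescaling, so group ratios and ANOVA F statistics are
    unchanged.
    """
    ref = table.loc[table[group_col] == youngest_group, measure]
    if ref.empty:
        raise ValueError(f"youngest group {youngest_group!r} not present")
    mean = float(ref.mean())
    if mean == 0:
        raise ValueError("youngest group mean is zero")
    out = table.copy()
    out[measure] = out[measure] * 100.0 / mean
    return out


def fold_change(
    table: pd.DataFrame,
    reference_group: str,
    comparison_group: str,
    measure: str,
    group_col: str = "group",
) -> float:
    """Ratio of group means: mean(comparison) / mean(reference)."""
    ref = table.loc[table[group_col] == reference_group, measure]
    comp = table.loc[table[group_col] == comparison_group, measure]
    if ref.empty or comp.empty:
        raise ValueError("reference or comparison group not present")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ValueError("reference group mean is zero")
    return float(comp.mean()) / ref_mean


@dataclass(frozen=True)
class BoxSummary:
    q1: float
    median: float
    q3: float
    minimum: float
    maximum: float


def summarize_box(values) -> BoxSummary:
    """Box-plot five-number summary: quartiles by linear interpolation
    between order statistics (inclusive method), whiskers at min/max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return BoxSummary(float(q1), float(med), float(q3),
                      float(v.min()), float(v.max()))
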