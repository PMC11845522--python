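"""Statistics over registration-accuracy rating tables.

Raters grade each (dataset, method) co-registration on a 6-point Likert
scale (1 = best possible alignment, 6 = no alignment / non-convergence)
with half-steps allowed.  This module computes the standard battery over
such tables: per-method summaries, insufficiency rates (grades >= 5),
one-way ANOVA with Bonferroni-corrected pairwise post-hoc comparisons and
pooled-SD Cohen's d, Welch's unequal-variance t-test, and pairwise
inter-rater agreement (Spearman rho and tie-corrected Kendall tau-b).

Conventions
-----------
* Cohen's d divides a pairwise mean difference by the *all-groups* pooled
  SD, the square root of the ANOVA within-group mean square (for equal
  group sizes, the root of the average group variance).
* The default ANOVA observation is the per-dataset mean grade across
  raters (one value per dataset and method); ``pooling="ratings"`` uses
  every individual grade instead.
* Bonferroni multiplies each pairwise p-value by the number of pairwise
  comparisons in the family, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import RatingRecord

__all__ = [
    "MethodSummary",
    "PosthocComparison",
    "AnovaResult",
    "ratings_frame",
    "summarize_methods",
    "insufficiency_rate",
    "method_groups",
    "anova_posthoc",
    "anova_posthoc_groups",
    "welch_t",
    "interrater_agreement",
    "total_coregistrations",
]


@dataclass(frozen=True)
class MethodSummary:
    method: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class PosthocComparison:
    method_a: str
    method_b: str
    mean_difference: float
    cohens_d: float
    p_bonferroni: float
    family_size: int


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pooled_sd: float
    comparisons: tuple


def ratings_frame(ratings: Iterable[RatingRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.dataset_id, r.method, r.rater_id, r.grade) for r in ratings],
        columns=["dataset_id", "method", "rater_id", "grade"],
    )
    if df.empty:
        raise ValueError("empty rating table")
    return df


def summarize_methods(ratings: Iterable[RatingRecord]) -> list[MethodSummary]:
    """Per-method mean and sample SD (n-1 denominator) over all grades."""
    df = ratings_frame(ratings)
    out = []
    for method, grp in df.groupby("method", sort=False):
        g = grp["grade"].to_numpy(float)
        sd = float(np.std(g, ddof=1)) if g.size > 1 else 0.0
        out.append(MethodSummary(str(method), int(g.size), float(np.mean(g)), sd))
    return out


def insufficiency_rate(
    ratings: Iterable[RatingRecord],
    method: str,
    cutoff: float = 5.0,
) -> tuple[int, float]:
    """Count and percentage of a method's grades at or above the cutoff.

    Grades of 5 and 6 mark insufficient registrations; half-steps at or
    above the cutoff (e.g. 5.5) are included.  The percentage is taken
    over all of that method's ratings (datasets x raters).
    """
    df = ratings_frame(ratings)
    g = df.loc[df["method"] == method, "grade"].to_numpy(float)
    if g.size == 0:
        raise ValueError(f"no ratings for method {method!r}")
    count = int(np.sum(g >= cutoff))
    return count, 100.0 * count / g.size


def total_coregistrations(ratings: Iterable[RatingRecord]) -> int:
    """Number of distinct rated co-registrations (dataset x method pairs)."""
    df = ratings_frame(ratings)
    return int(df.drop_duplicates(["dataset_id", "method"]).shape[0])


def method_groups(
    ratings: Iterable[RatingRecord],
    pooling: str = "dataset_mean",
) -> dict[str, np.ndarray]:
    """Per-method observation vectors for the ANOVA.

    ``"dataset_mean"`` (default) averages each dataset's grades across
    raters, giving one observation per dataset and method;
    ``"ratings"`` keeps every individual grade as an observation.
    """
    df = ratings_frame(ratings)
    if pooling == "dataset_mean":
        obs = df.groupby(["method", "dataset_id"], sort=False)["grade"].mean()
        return {
            str(m): obs.loc[m].to_numpy(float) for m in df["method"].unique()
        }
    if pooling == "ratings":
        return {
            str(m): grp["grade"].to_numpy(float)
            for m, grp in df.groupby("method", sort=False)
        }
    raise ValueError(f"unknown pooling {pooling!r}")


def anova_posthoc_groups(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with Bonferroni post-hoc on raw groups.

    Post-hoc t statistics use the within-group mean square as the common
    variance (classical Fisher-LSD statistic, Bonferroni-adjusted);
    Cohen's d divides each mean difference by the pooled (within-group)
    SD.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(arrays.values()))
    n_total = all_vals.size
    k = len(names)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
        p = 1.0 if ms_between == 0 else 0.0
    else:
        f_stat = float(ms_between / ms_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    pooled_sd = float(np.sqrt(ms_within))

    pairs = list(combinations(names, 2))
    family = len(pairs)
    comparisons = []
    for a_name, b_name in pairs:
        a, b = arrays[a_name], arrays[b_name]
        diff = float(a.mean() - b.mean())
        d = diff / pooled_sd if pooled_sd > 0 else 0.0
        if ms_within > 0:
            t = diff / np.sqrt(ms_within * (1.0 / a.size + 1.0 / b.size))
            p_raw = 2.0 * float(stats.t.sf(abs(t), df_within))
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        comparisons.append(
            PosthocComparison(
                a_name,
                b_name,
                diff,
                float(d),
                min(1.0, family * p_raw),
                family,
            )
        )
    return AnovaResult(f_stat, df_between, df_within, p, pooled_sd, tuple(comparisons))


def anova_posthoc(
    ratings: Iterable[RatingRecord],
    pooling: str = "dataset_mean",
) -> AnovaResult:
    """One-way ANOVA of grade by registration method, with post-hoc battery."""
    return anova_posthoc_groups(method_groups(ratings, pooling=pooling))


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def interrater_agreement(
    ratings: Iterable[RatingRecord],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Pairwise inter-rater agreement over shared (dataset, method) items.

    Returns one row per rater pair with Spearman's rho (average ranks for
    ties) and Kendall's tau-b (tie-corrected), each with its p-value.
    """
    df = ratings_frame(ratings)
    wide = df.pivot_table(
        index=["dataset_id", "method"], columns="rater_id", values="grade"
    )
    raters = list(wide.columns)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    rows = []
    for ra, rb in combinations(raters, 2):
        both = wide[[ra, rb]].dropna()
        if both.shape[0] < min_overlap:
            raise ValueError(
                f"raters {ra!r} and {rb!r} share only {both.shape[0]} items (< {min_overlap})"
            )
        x = both[ra].to_numpy(float)
        y = both[rb].to_numpy(float)
        rho = stats.spearmanr(x, y)
        tau = stats.kendalltau(x, y, variant="b")
        rows.append(
            {
                "rater_a": ra,
                "rater_b": rb,
                "n_items": int(both.shape[0]),
                "spearman_rho": float(rho.statistic),
                "spearman_p": float(rho.pvalue),
                "kendall_tau": float(tau.statistic),
                "kendall_p": float(tau.pvalue),
            }
        )
    return pd.DataFrame(rows)
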