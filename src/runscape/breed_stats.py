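"""Across-population comparisons: one-way ANOVA with Tukey HSD letters, and
Pearson tests between per-sample ROH and ROHet burden.

Tukey HSD uses the studentized-range distribution with Tukey–Kramer standard
errors for unbalanced groups (scipy's numerical implementation); group-mean
differences at a shared significance letter are not significant at the given
alpha.  A rank-based fallback (Kruskal–Wallis with Dunn-style pairwise rank
tests, Bonferroni-adjusted) is available for count-like responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .runs import RunSet


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    """Result of an all-pairs group comparison."""

    group_stats: pd.DataFrame  # group, n, mean, sd
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, p_value, significant
    letters: dict[str, str]
    alpha: float
    method: str


def _compact_letters(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must already be in deterministic display order; groups share
    a letter iff their difference is not significant.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        new_sets: list[set[str]] = []
        changed = False
        for s in sets:
            if a in s and b in s:
                changed = True
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        if changed:
            # absorb: drop sets contained in another set
            sets = [
                s for s in new_sets
                if s and not any(s < t for t in new_sets)
            ]
            # deduplicate while preserving order
            seen: list[set[str]] = []
            for s in sets:
                if s not in seen:
                    seen.append(s)
            sets = seen
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters: dict[str, str] = {g: "" for g in groups}
    for rank, s in enumerate(sets):
        letter = chr(ord("a") + rank) if rank < 26 else f"z{rank}"
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def anova_tukey(
    values: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
    method: str = "tukey",
) -> GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD and compact letters.

    ``method='kruskal'`` swaps in Kruskal–Wallis plus pairwise Mann–Whitney
    tests with Bonferroni adjustment (rank-based fallback for counts).
    Groups are displayed in order of decreasing mean (ties broken by label).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(group_labels).astype(str)
    if v.shape != lab.shape:
        raise StatsError("values and labels differ in length")
    if method not in ("tukey", "kruskal"):
        raise StatsError(f"unknown method {method!r}")
    labels = sorted(set(lab.tolist()))
    if len(labels) < 2:
        raise StatsError("need at least two groups")
    samples = {g: v[lab == g] for g in labels}
    for g, x in samples.items():
        if x.size < 2:
            raise StatsError(f"group {g!r} has fewer than 2 observations")
    display = sorted(labels, key=lambda g: (-float(np.mean(samples[g])), g))
    group_stats = pd.DataFrame(
        {
            "group": display,
            "n": [samples[g].size for g in display],
            "mean": [float(np.mean(samples[g])) for g in display],
            "sd": [float(np.std(samples[g], ddof=1)) for g in display],
        }
    )

    within_var = sum(
        float(np.var(samples[g], ddof=1)) * (samples[g].size - 1) for g in labels
    )
    rows = []
    if within_var == 0.0:
        # degenerate: no within-group spread; differences are all-or-nothing
        means = {g: float(np.mean(samples[g])) for g in labels}
        if len(set(means.values())) == 1:
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = float("inf"), 0.0
        for a, b in combinations(display, 2):
            p = 1.0 if means[a] == means[b] else 0.0
            rows.append((a, b, p, p < alpha))
    elif method == "tukey":
        f_stat, p_val = stats.f_oneway(*(samples[g] for g in labels))
        res = stats.tukey_hsd(*(samples[g] for g in labels))
        pos = {g: i for i, g in enumerate(labels)}
        for a, b in combinations(display, 2):
            p = float(res.pvalue[pos[a], pos[b]])
            rows.append((a, b, p, p < alpha))
    else:
        f_stat, p_val = stats.kruskal(*(samples[g] for g in labels))
        n_pairs = len(labels) * (len(labels) - 1) // 2
        for a, b in combinations(display, 2):
            p = float(
                stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue
            )
            p = min(1.0, p * n_pairs)
            rows.append((a, b, p, p < alpha))

    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "p_value", "significant"]
    )
    significant = {
        tuple(sorted((r.group_a, r.group_b)))
        for r in pairwise.itertuples()
        if r.significant
    }
    letters = _compact_letters(display, significant)
    return GroupComparison(
        group_stats=group_stats,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        method=method,
    )


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise StatsError("need at least 3 pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise StatsError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def class_count_comparison(
    runset: RunSet, samples: pd.DataFrame, alpha: float = 0.05,
    method: str = "tukey",
) -> pd.DataFrame:
    """Per length class: population means +- SD of per-sample run counts with
    Tukey letters (the layout of a per-breed run-count table).

    Zero-run samples count as zeros; ``samples`` provides the full cohort.
    """
    df = runset.to_frame()
    sids = samples["sample_id"].astype(str)
    pops = samples["population"].astype(str)
    classes = list(df["class"].unique())
    rows = []
    for cls in classes:
        sub = df[df["class"] == cls]
        counts = sub.groupby("sample").size()
        per_sample = np.array([counts.get(s, 0) for s in sids], dtype=float)
        cmp = anova_tukey(per_sample, pops.to_numpy(), alpha=alpha, method=method)
        for rec in cmp.group_stats.itertuples():
            rows.append(
                {
                    "class": cls,
                    "population": rec.group,
                    "n_samples": rec.n,
                    "mean_count": rec.mean,
                    "sd_count": rec.sd,
                    "letters": cmp.letters[rec.group],
                    "anova_p": cmp.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["class", "population", "n_samples", "mean_count", "sd_count",
                 "letters", "anova_p"],
    )


def roh_rohet_correlation(
    roh_runs: RunSet,
    rohet_runs: RunSet,
    samples: pd.DataFrame,
    measure: str = "length",
) -> pd.DataFrame:
    """Per-population Pearson correlation between per-sample ROH and ROHet
    burden (summed bp by default, run counts with ``measure='count'``)."""
    if measure not in ("length", "count"):
        raise StatsError(f"unknown burden measure {measure!r}")

    def _burden(runset: RunSet) -> pd.Series:
        df = runset.to_frame()
        if measure == "length":
            return df.groupby("sample")["length_bp"].sum()
        return df.groupby("sample").size().astype(float)

    b_roh = _burden(roh_runs)
    b_rohet = _burden(rohet_runs)
    rows = []
    for pop, grp in samples.groupby("population"):
        ids = grp["sample_id"].astype(str)
        x = np.array([b_roh.get(s, 0.0) for s in ids], dtype=float)
        y = np.array([b_rohet.get(s, 0.0) for s in ids], dtype=float)
        if ids.size < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
            r, p = np.nan, np.nan
        else:
            r, p = pearson_test(x, y)
        rows.append({"population": pop, "n": int(ids.size), "r": r, "p_value": p})
    return pd.DataFrame(rows, columns=["population", "n", "r", "p_value"])
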