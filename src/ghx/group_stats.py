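"""Between-class comparison of linker features.

Descriptive statistics (median and quartiles by linear interpolation,
mean +/- sample SD) plus one-way ANOVA with Tukey's HSD post-hoc test, and a
rank-based Mann-Whitney companion for two-group robustness checks.
Significance codes follow the conventional ladder: ns (p > 0.05),
* (p < 0.05), ** (p < 0.01), *** (p < 0.001), **** (p < 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ghx.linker_features import LinkerFeatures, dominant_residues


@dataclass
class GroupDescriptives:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float


@dataclass
class GroupComparison:
    """Descriptive and inferential statistics for one feature across classes."""

    feature: str
    groups: dict[str, GroupDescriptives]
    f_statistic: float
    p_value: float
    tukey_p: dict[tuple[str, str], float]
    significance: str
    mannwhitney_p: Optional[float] = None  # two-group companion, not part of the primary analysis
    notes: list[str] = field(default_factory=list)


def describe(values: Sequence[float], group_name: str = "") -> GroupDescriptives:
    """Median/quartiles (linear interpolation, 'type-7') and mean +/- sample SD."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"empty group {group_name!r}")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return GroupDescriptives(
        n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3),
        mean=float(arr.mean()), sd=sd,
    )


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """Classical one-way ANOVA plus Tukey HSD adjusted pairwise p-values.

    Convention for degenerate input: when every group has zero within-group
    variance and the group means are all equal, F = 0 and p = 1 (no evidence
    of a difference, rather than 0/0).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=np.float64) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    means = [a.mean() for a in arrays]
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if ssw == 0.0 and np.ptp(means) == 0.0:
        pairwise = {tuple(sorted((a, b))): 1.0 for i, a in enumerate(names) for b in names[i + 1:]}
        return 0.0, 1.0, pairwise

    f_stat, p_val = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            key = tuple(sorted((names[i], names[j])))
            pairwise[key] = float(res.pvalue[i, j])
    return float(f_stat), float(p_val), pairwise


def significance_code(p: float) -> str:
    """Map a p-value onto the ns/*/**/***/**** ladder (strict inequalities).

    A boundary value such as p = 0.05 is 'ns' because significance requires
    p strictly below the threshold.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


DEFAULT_FEATURES = ("length", "n_sequons", "n_glycosylatable")


def compare_classes(
    features: Sequence[LinkerFeatures],
    k_dominant: int = 6,
    feature_names: Optional[Sequence[str]] = None,
) -> list[GroupComparison]:
    """Compare linker features between taxonomic classes.

    By default compares linker length, sequon counts, and per-residue counts
    of the ``k_dominant`` most abundant residues (pooled over all linkers).
    Records without a class label are excluded (count noted on each result).

    Raises
    ------
    ValueError
        If fewer than two labeled classes with n >= 2 are present.
    """
    labeled = [f for f in features if f.class_label is not None]
    n_dropped = len(features) - len(labeled)
    by_class: dict[str, list[LinkerFeatures]] = {}
    for f in labeled:
        by_class.setdefault(f.class_label, []).append(f)
    by_class = {c: fs for c, fs in by_class.items() if len(fs) >= 2}
    if len(by_class) < 2:
        raise ValueError("need >= 2 labeled classes with n >= 2 each")

    if feature_names is None:
        feature_names = list(DEFAULT_FEATURES) + [
            f"count_{aa}" for aa in dominant_residues(labeled, k_dominant)
        ]

    def extract(f: LinkerFeatures, name: str) -> float:
        if name == "length":
            return float(f.length)
        if name == "n_sequons":
            return float(f.n_sequons)
        if name == "n_glycosylatable":
            return float(f.n_glycosylatable)
        if name.startswith("count_"):
            return float(f.counts.get(name[len("count_"):], 0))
        raise ValueError(f"unknown feature {name!r}")

    results = []
    class_names = sorted(by_class)
    for name in feature_names:
        groups = {c: [extract(f, name) for f in by_class[c]] for c in class_names}
        f_stat, p_val, tukey = anova_tukey(groups)
        mw_p = None
        if len(class_names) == 2:
            a, b = (groups[c] for c in class_names)
            if np.ptp(a + b) > 0:
                mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        comp = GroupComparison(
            feature=name,
            groups={c: describe(groups[c], c) for c in class_names},
            f_statistic=f_stat,
            p_value=p_val,
            tukey_p=tukey,
            significance=significance_code(p_val),
            mannwhitney_p=mw_p,
        )
        if n_dropped:
            comp.notes.append(f"{n_dropped} unlabeled records excluded")
        results.append(comp)
    return results


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into one row per feature for TSV export."""
    rows = []
    for c in comparisons:
        row: dict[str, object] = {"feature": c.feature}
        for g, d in sorted(c.groups.items()):
            row[f"{g}_n"] = d.n
            row[f"{g}_median"] = d.median
            row[f"{g}_q1"] = d.q1
            row[f"{g}_q3"] = d.q3
            row[f"{g}_mean"] = round(d.mean, 6)
            row[f"{g}_sd"] = round(d.sd, 6)
        row["anova_F"] = round(c.f_statistic, 6)
        row["anova_p"] = f"{c.p_value:.6g}"
        row["significance"] = c.significance
        row["mannwhitney_p"] = "NA" if c.mannwhitney_p is None else f"{c.mannwhitney_p:.6g}"
        rows.append(row)
    return pd.DataFrame(rows)
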