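"""Group comparisons and the expression fold-change filter.

The statistical toolkit of the study: unpaired Student's t-test (pooled
variance, one- or two-tailed; Welch behind a flag), one-way ANOVA with
Tukey's HSD post hoc test for the multi-genotype MRI comparisons,
mean + SEM group summaries, and the 1.8-fold-change filter that selects
genes modulated between late (day 3–5) and early (day 1.5–2) trophoblast
cultures on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError, DataError

__all__ = [
    "GroupTable",
    "ExpressionMatrix",
    "TTestResult",
    "AnovaResult",
    "FoldChangeSelection",
    "t_test",
    "anova_tukey",
    "summarize_groups",
    "fold_change_filter",
]

DEFAULT_FOLD_THRESHOLD = 1.8


@dataclass(frozen=True)
class GroupTable:
    """Tidy table of one measurement across experimental units and groups."""

    data: pd.DataFrame  # columns: unit_id, group, value
    measurement: str = "value"

    def __post_init__(self) -> None:
        required = {"unit_id", "group", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"group table missing columns: {sorted(missing)}")
        if self.data.empty:
            raise DataError("empty group table")
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise DataError("non-finite measurement values")

    @classmethod
    def from_dict(cls, groups: Mapping[str, Sequence[float]], measurement: str = "value") -> "GroupTable":
        rows = [
            {"unit_id": f"{label}_{i}", "group": label, "value": float(v)}
            for label, values in groups.items()
            for i, v in enumerate(values)
        ]
        return cls(pd.DataFrame(rows), measurement=measurement)

    def groups(self) -> dict[str, np.ndarray]:
        return {
            str(label): sub["value"].to_numpy(dtype=float)
            for label, sub in self.data.groupby("group", sort=True)
        }


@dataclass(frozen=True)
class ExpressionMatrix:
    """Linear-scale expression values (genes × samples) with group labels.

    ``groups`` maps each sample (column) to ``"early"`` or ``"late"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.hasnans or self.values.index.duplicated().any():
            raise DataError("gene identifiers must be unique and non-missing")
        if set(self.values.columns) != set(self.groups.index):
            raise DataError("sample sheet does not match expression columns")
        labels = set(self.groups)
        if not labels <= {"early", "late"}:
            raise DataError(f"unknown group labels: {sorted(labels - {'early', 'late'})}")
        if "early" not in labels or "late" not in labels:
            raise DataError("both an 'early' and a 'late' group are required")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise DataError("expression values must be non-negative (linear scale)")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    direction: Literal["A>B", "A<B", "none"]
    tails: int
    degenerate: bool = False


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    tails: int = 2,
    alternative: Literal["greater", "less"] = "greater",
    welch: bool = False,
) -> TTestResult:
    """Unpaired Student's t-test (pooled variance; Welch behind a flag).

    For ``tails=1`` the alternative states the hypothesized direction of
    group A relative to group B; the one-tailed p equals half the
    two-tailed p when the observed effect lies in that direction.

    Zero pooled variance is handled by convention: equal means give
    ``t=0, p=1``; unequal means give an infinite t with ``p=0`` and the
    degenerate flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs n >= 2 for a t-test")
    if tails not in (1, 2):
        raise ConfigError(f"tails must be 1 or 2, got {tails}")
    diff = a.mean() - b.mean()
    direction: Literal["A>B", "A<B", "none"]
    direction = "A>B" if diff > 0 else ("A<B" if diff < 0 else "none")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, "none", tails, degenerate=False)
        return TTestResult(float(np.sign(diff) * np.inf), 0.0, direction, tails,
                           degenerate=True)
    if tails == 2:
        res = sps.ttest_ind(a, b, equal_var=not welch)
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return TTestResult(float(res.statistic), float(res.pvalue), direction, tails)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, lower, upper, reject


def anova_tukey(table: GroupTable) -> AnovaResult:
    """One-way ANOVA followed by Tukey's HSD across all group pairs.

    When every observation is identical the F statistic is 0 with p = 1
    (and all adjusted pairwise p-values are 1) by convention, since the
    variance ratio is undefined.
    """
    groups = table.groups()
    if len(groups) < 2:
        raise DataError("ANOVA requires >= 2 groups")
    for label, values in groups.items():
        if values.size < 2:
            raise DataError(f"group {label!r} has n < 2")
    labels = sorted(groups)
    values_all = np.concatenate([groups[g] for g in labels])
    if np.ptp(values_all) == 0:
        pairs = [
            {"group1": g1, "group2": g2, "meandiff": 0.0, "p_adj": 1.0,
             "lower": 0.0, "upper": 0.0, "reject": False}
            for i, g1 in enumerate(labels) for g2 in labels[i + 1 :]
        ]
        return AnovaResult(0.0, 1.0, pd.DataFrame(pairs))
    f, p = sps.f_oneway(*(groups[g] for g in labels))
    codes = np.concatenate([[g] * groups[g].size for g in labels])
    hsd = pairwise_tukeyhsd(values_all, codes)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    tukey["p_adj"] = hsd.pvalues
    return AnovaResult(float(f), float(p), tukey)


def summarize_groups(table: GroupTable) -> pd.DataFrame:
    """Per-group mean and SEM (sd/√n); single-unit groups get SEM 0, flagged."""
    rows = []
    for label, values in table.groups().items():
        n = values.size
        sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {"group": label, "n": n, "mean": float(values.mean()), "sem": sem,
             "sem_flagged": n == 1}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldChangeSelection:
    """Genes passing the fold-change filter plus excluded degenerate genes."""

    selected: pd.DataFrame  # columns: gene, fold, log2_fold, direction
    all_folds: pd.DataFrame
    excluded: tuple[str, ...]  # genes with zero early-group mean


def fold_change_filter(
    expr: ExpressionMatrix,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> FoldChangeSelection:
    """Select genes modulated by at least ``threshold``-fold between groups.

    The fold change of a gene is mean(late)/mean(early) on the linear
    scale; a gene is selected when its fold change is >= threshold or
    <= 1/threshold (boundary inclusive). Output is sorted by |log2 fold|
    descending, ties broken by gene identifier. Genes whose early-group
    mean is zero have no defined ratio: they are excluded from the ratio
    table and reported separately.
    """
    if threshold <= 1:
        raise ConfigError(f"fold threshold must exceed 1, got {threshold}")
    early = expr.values[expr.samples("early")].mean(axis=1)
    late = expr.values[expr.samples("late")].mean(axis=1)
    degenerate = early == 0
    excluded = tuple(early.index[degenerate])
    early, late = early[~degenerate], late[~degenerate]
    fold = late / early
    with np.errstate(divide="ignore"):
        log2_fold = np.log2(fold.to_numpy())
    table = pd.DataFrame(
        {
            "gene": fold.index,
            "fold": fold.to_numpy(),
            "log2_fold": log2_fold,
            "direction": np.where(fold.to_numpy() >= 1, "up", "down"),
        }
    )
    table["abs_log2"] = np.abs(table["log2_fold"])
    table = table.sort_values(
        ["abs_log2", "gene"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_log2").reset_index(drop=True)
    keep = (table["fold"] >= threshold) | (table["fold"] <= 1.0 / threshold)
    return FoldChangeSelection(
        selected=table[keep].reset_index(drop=True),
        all_folds=table,
        excluded=excluded,
    )
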