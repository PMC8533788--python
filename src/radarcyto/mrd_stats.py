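"""MRD quantification and the statistics battery.

Blast percentages of syto-positive nucleated events are binned into the
flow-MRD risk categories used at Day 15 (FLR < 0.1%, FMR 0.1-<10%,
FHR >= 10%) and the same boundaries unnamed at Day 33. Paired method /
examiner comparisons route through Shapiro-Wilk to a paired t-test or a
Wilcoxon signed-rank test and always report Spearman's correlation.
Position-genetics and homogeneity-genetics associations use Pearson's
chi-square on the contingency table plus pairwise two-proportion
z-tests. Two-sided tests throughout; pairwise p-values are reported raw
(no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .fcs_io import EventMatrix

__all__ = [
    "AssociationResult",
    "MRDResult",
    "PairedComparison",
    "association_homogeneity_genetics",
    "association_position_genetics",
    "categorize_mrd",
    "cohort_summary",
    "compare_paired",
    "quantify_blasts",
    "round_half_up",
    "two_proportion_z",
]

#: category boundaries in percent: <0.1 / [0.1, 10) / >=10
MRD_BOUNDS = (0.1, 10.0)
_DAY15_NAMES = ("FLR", "FMR", "FHR")
_DAY33_NAMES = ("lt0.1", "mid", "ge10")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding (half away from zero), e.g. 16.65 -> 16.7."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MRDResult:
    blast_pct: float
    category: str
    timepoint: str

    def __post_init__(self):
        if not 0.0 <= self.blast_pct <= 100.0:
            raise ValueError("blast_pct must be in [0, 100]")
        if self.category != categorize_mrd(self.blast_pct, self.timepoint):
            raise ValueError("category inconsistent with blast_pct")


@dataclass
class PairedComparison:
    test_used: str  # "paired_t" | "wilcoxon"
    statistic: float
    p_value: float
    spearman_r: float
    spearman_p: float
    normality_p: float
    spearman_undefined: bool = False


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame
    pairwise: list[tuple] = field(default_factory=list)
    # pairwise rows: (group_a, group_b, level, z, p)


def categorize_mrd(blast_pct: float, timepoint: str = "day15") -> str:
    """Flow-MRD category; boundaries are inclusive at 0.1 and 10."""
    names = _DAY15_NAMES if timepoint == "day15" else _DAY33_NAMES
    if blast_pct < MRD_BOUNDS[0]:
        return names[0]
    if blast_pct < MRD_BOUNDS[1]:
        return names[1]
    return names[2]


def quantify_blasts(blast_mask: np.ndarray, nucleated_mask: np.ndarray,
                    timepoint: str = "day15") -> MRDResult:
    """Blast percentage of syto-positive nucleated events (the standard
    flow-MRD denominator) with its risk category."""
    blast_mask = np.asarray(blast_mask, dtype=bool)
    nucleated_mask = np.asarray(nucleated_mask, dtype=bool)
    if blast_mask.shape != nucleated_mask.shape:
        raise ValueError("masks must have equal length")
    denom = int(nucleated_mask.sum())
    if denom == 0:
        raise ValueError("empty nucleated mask")
    pct = 100.0 * float((blast_mask & nucleated_mask).sum()) / denom
    return MRDResult(pct, categorize_mrd(pct, timepoint), timepoint)


def compare_paired(x: Sequence[float], y: Sequence[float],
                   alpha: float = 0.05) -> PairedComparison:
    """Paired two-group comparison with normality-routed test choice.

    Shapiro-Wilk on the paired differences decides the test: paired
    Student's t when normality is not rejected at ``alpha``, Wilcoxon
    signed-rank otherwise. Spearman's correlation is always reported.
    All-zero differences yield p = 1.0 by convention, with the Spearman
    part flagged undefined when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 6:
        raise ValueError("need at least 6 pairs (Shapiro-Wilk minimum)")
    d = y - x

    spearman_undefined = False
    if np.all(x == x[0]) or np.all(y == y[0]):
        r = p_r = float("nan")
        spearman_undefined = True
    else:
        r, p_r = stats.spearmanr(x, y)

    if np.all(d == 0):
        return PairedComparison("paired_t", 0.0, 1.0, float(r), float(p_r),
                                normality_p=1.0,
                                spearman_undefined=spearman_undefined)

    if np.all(d == d[0]):
        # constant nonzero shift: Shapiro is undefined, but the shift is
        # maximally systematic — route to Wilcoxon (distribution-free)
        norm_p = 0.0
    else:
        norm_p = float(stats.shapiro(d).pvalue)
    if norm_p >= alpha:
        res = stats.ttest_rel(y, x)
        return PairedComparison("paired_t", float(res.statistic),
                                float(res.pvalue), float(r), float(p_r),
                                normality_p=norm_p,
                                spearman_undefined=spearman_undefined)
    res = stats.wilcoxon(y, x, zero_method="wilcox", method="auto")
    return PairedComparison("wilcoxon", float(res.statistic),
                            float(res.pvalue), float(r), float(p_r),
                            normality_p=norm_p,
                            spearman_undefined=spearman_undefined)


def two_proportion_z(x_a: int, n_a: int, x_b: int, n_b: int
                     ) -> tuple[float, float]:
    """Two-sided two-proportion z-test; equal proportions give (0, 1)."""
    if min(n_a, n_b) <= 0:
        raise ValueError("group sizes must be positive")
    if x_a * n_b == x_b * n_a:  # identical proportions (incl. 0/0 pools)
        return 0.0, 1.0
    z, p = proportions_ztest([x_a, x_b], [n_a, n_b])
    return float(z), float(p)


def _association(table: pd.DataFrame) -> AssociationResult:
    counts = table.to_numpy(dtype=float)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(
            "degenerate contingency table: need >=2 nonzero levels per axis")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    result = AssociationResult(float(chi2), int(dof), float(p), table)
    groups = list(table.index)
    totals = table.sum(axis=1)
    for level in table.columns:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if totals[a] == 0 or totals[b] == 0:
                    continue
                z, pz = two_proportion_z(
                    int(table.loc[a, level]), int(totals[a]),
                    int(table.loc[b, level]), int(totals[b]))
                result.pairwise.append((a, b, level, z, pz))
    return result


def association_position_genetics(cases: Iterable,
                                  tube: int = 1) -> AssociationResult:
    """Chi-square association of radar position x cytogenetic subtype,
    with per-gate pairwise two-proportion z-tests between subtypes.

    ``cases`` yields objects with ``subtype`` and a position attribute
    (``assigned_position`` when the pipeline filled it, else the planted
    ``position_tube1``/``position_tube2`` of the requested tube).
    """
    rows = []
    for c in cases:
        pos = getattr(c, "assigned_position", None)
        if pos is None:
            pos = getattr(c, f"position_tube{tube}")
        rows.append((c.subtype, int(pos)))
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows, columns=["subtype", "position"])
    table = pd.crosstab(df["subtype"], df["position"])
    return _association(table)


def association_homogeneity_genetics(cases: Iterable) -> AssociationResult:
    """Chi-square association of homogeneous/heterogeneous x subtype."""
    rows = []
    for c in cases:
        het = getattr(c, "heterogeneous", None)
        if het is None:
            het = c.n_subclones > 1
        rows.append((c.subtype, "heterogeneous" if het else "homogeneous"))
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows, columns=["subtype", "homogeneity"])
    table = pd.crosstab(df["subtype"], df["homogeneity"])
    return _association(table)


def cohort_summary(categories: Mapping[str, int] | Iterable[str],
                   total: int | None = None) -> pd.DataFrame:
    """Counts and display percentages per category.

    Accepts either per-case category labels or a mapping of counts.
    Percentages are 100*count/total rounded half-up to one decimal.
    """
    if isinstance(categories, Mapping):
        counts = dict(categories)
    else:
        labels = list(categories)
        counts = dict(pd.Series(labels, dtype=object).value_counts(
            sort=False))
    if not counts:
        raise ValueError("empty cohort")
    if total is None:
        total = int(sum(counts.values()))
    if total <= 0:
        raise ValueError("total must be positive")
    df = pd.DataFrame(
        {
            "n": pd.Series(counts, dtype=int),
            "pct": pd.Series(
                {k: round_half_up(100.0 * v / total, 1)
                 for k, v in counts.items()}
            ),
        }
    )
    df.index.name = "category"
    return df
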