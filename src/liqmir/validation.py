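"""Targeted-marker statistics: group comparisons, ROC/Youden, performance
metrics, combined-marker decision rules, correlations and paired fluid tests.

Conventions fixed across the package:

* "above the cutoff" is strict (``>``), mirroring the strict ``Ct < T``
  detection rule used upstream;
* ROC thresholds are the observed marker values plus ±infinity sentinels,
  the reported Youden cutoff is the midpoint between the two observed values
  bracketing the optimum, and Youden ties are broken toward higher
  specificity (a QC-friendly choice: do not discard clean samples);
* report percentages use half-up rounding to one decimal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CtMatrix, SampleMeta

__all__ = [
    "RocResult",
    "PerfMetrics",
    "MarkerRule",
    "GroupComparison",
    "round_half_up",
    "compare_groups",
    "roc",
    "confusion_metrics",
    "apply_marker_rule",
    "correlate",
    "paired_fluid_comparison",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (2.25 -> 2.3), as printed in report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """ROC over observed thresholds with the Youden operating point.

    ``points`` holds (threshold, tpr, fpr) sorted by threshold ascending;
    a sample is called positive when its value is strictly above the
    threshold.  ``auc`` is the trapezoidal area over (fpr, tpr), identical
    to the Mann-Whitney concordance U/(n1*n2).
    """

    auc: float
    points: tuple[tuple[float, float, float], ...]
    youden_cutoff: float
    j_statistic: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


def roc(values: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Build the ROC of a marker; higher value = more case-like.

    Raises ``ValueError`` when only one class is present.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC")

    uniq = np.unique(v)
    # candidate cutoffs: below the minimum, midpoints, above the maximum
    cuts = np.concatenate((
        [uniq[0] - 1.0],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 1.0],
    ))
    pts = []
    for c in cuts:
        pred = v > c
        tpr = float((pred & y).sum() / n_pos)
        fpr = float((pred & ~y).sum() / n_neg)
        pts.append((float(c), tpr, fpr))
    pts.sort(key=lambda p: p[0])

    # descending threshold = ascending (fpr, tpr): the proper ROC path
    path = pts[::-1]
    fprs = np.array([p[2] for p in path])
    tprs = np.array([p[1] for p in path])
    auc = float(np.trapezoid(tprs, fprs))

    tprs_t = np.array([p[1] for p in pts])
    fprs_t = np.array([p[2] for p in pts])
    j = tprs_t - fprs_t
    best_j = float(j.max())
    # ties toward higher specificity = lower fpr = higher threshold
    candidates = [p for p, ji in zip(pts, j) if ji >= best_j - 1e-12]
    best = max(candidates, key=lambda p: (-p[2], p[0]))
    return RocResult(
        auc=auc,
        points=tuple(pts),
        youden_cutoff=best[0],
        j_statistic=best_j,
        sensitivity_at_cutoff=best[1],
        specificity_at_cutoff=1.0 - best[2],
    )


# ---------------------------------------------------------------------------
# Confusion-matrix performance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerfMetrics:
    """Confusion-matrix performance; ratios with a zero denominator are None."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_percent(self, decimals: int = 1) -> dict[str, float | None]:
        """The five ratios as half-up-rounded percentages."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            val = getattr(self, name)
            out[name] = None if val is None else round_half_up(100 * val, decimals)
        return out


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> PerfMetrics:
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("at least one count must be positive")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return PerfMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=ratio(tp + tn, total),
    )


# ---------------------------------------------------------------------------
# Combined-marker decision rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerRule:
    """Threshold rule over one or more markers on the log2 relative scale.

    ``any_above`` calls a sample positive when at least one marker exceeds
    its cutoff; ``all_above`` when every marker does; ``single`` is a plain
    one-marker threshold.
    """

    markers: tuple[str, ...]
    cutoffs: tuple[float, ...]
    combiner: str = "single"

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.cutoffs):
            raise ValueError("one cutoff per marker required")
        if self.combiner not in ("any_above", "all_above", "single"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.combiner == "single" and len(self.markers) != 1:
            raise ValueError("'single' rule takes exactly one marker")


def apply_marker_rule(rel: pd.DataFrame, rule: MarkerRule) -> pd.Series:
    """Apply a marker rule to a relative-quantification table.

    ``rel`` must carry columns ``sample_id``, ``assay``, ``log2_rel``.
    Returns a boolean Series indexed by sample_id; samples missing any rule
    marker get a null call with a warning.
    """
    wide = rel.pivot_table(index="sample_id", columns="assay",
                           values="log2_rel", aggfunc="mean")
    missing_assays = [m for m in rule.markers if m not in wide.columns]
    if missing_assays:
        raise ValueError(f"markers not quantified: {missing_assays}")
    sub = wide[list(rule.markers)]
    above = sub.gt(pd.Series(rule.cutoffs, index=list(rule.markers)), axis=1)
    complete = sub.notna().all(axis=1)
    if rule.combiner == "all_above":
        calls = above.all(axis=1)
    else:  # any_above or single
        calls = above.any(axis=1)
    calls = calls.astype(object)
    if (~complete).any():
        warnings.warn(
            f"{int((~complete).sum())} sample(s) missing a marker value; "
            "call set to null", stacklevel=2,
        )
        calls[~complete] = None
    calls.name = "positive"
    return calls


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Result of a non-parametric group comparison."""

    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    adjustment: str | None = None
    warning: str | None = None


def _holm(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def _dunn(groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    Z statistics use pooled mean ranks with the standard tie correction;
    two-tailed p-values are Holm-adjusted over all pairwise comparisons.
    """
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12 * (n - 1))) if n > 1 else 0.0
    mean_ranks, sizes, offset = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[offset:offset + len(g)].mean())
        sizes.append(len(g))
        offset += len(g)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _holm(df["p_raw"].tolist())
    return df


def compare_groups(
    groups: Sequence[Sequence[float]],
    paired: bool = False,
) -> GroupComparison:
    """Non-parametric comparison of 2+ groups.

    Two groups: Mann-Whitney U (or Wilcoxon signed-rank when paired).
    More: Kruskal-Wallis followed by Dunn's pairwise test with Holm-adjusted
    two-tailed p-values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            test="degenerate", statistic=float("nan"), p_value=1.0,
            warning="all values tied; p set to 1",
        )
    if len(arrays) == 2:
        if paired:
            if len(arrays[0]) != len(arrays[1]):
                raise ValueError("paired comparison requires equal lengths")
            diffs = arrays[0] - arrays[1]
            if np.all(diffs == 0):
                return GroupComparison(
                    test="wilcoxon", statistic=float("nan"), p_value=1.0,
                    warning="all paired differences zero; p set to 1",
                )
            res = stats.wilcoxon(arrays[0], arrays[1], alternative="two-sided")
            return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupComparison("mannwhitneyu", float(res.statistic), float(res.pvalue))
    if paired:
        res = stats.friedmanchisquare(*arrays)
        name = "friedman"
    else:
        res = stats.kruskal(*arrays)
        name = "kruskal"
    pairwise = _dunn(arrays)
    return GroupComparison(
        test=name, statistic=float(res.statistic), p_value=float(res.pvalue),
        pairwise=pairwise, adjustment="holm",
    )


# ---------------------------------------------------------------------------
# Correlation and paired-fluid comparison
# ---------------------------------------------------------------------------

def correlate(x: Sequence[float], y: Sequence[float]) -> dict[str, float | None]:
    """Spearman rank correlation with two-tailed p.

    Constant input leaves rho undefined (None), never zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": None, "p_value": None, "n": len(x)}
    res = stats.spearmanr(x, y)
    return {"rho": float(res.statistic), "p_value": float(res.pvalue), "n": len(x)}


def paired_fluid_comparison(
    matrix: CtMatrix,
    meta: Sequence[SampleMeta],
    assays: Sequence[str],
) -> pd.DataFrame:
    """Per-assay paired comparison of Ct values across matched fluids.

    Pairs are defined by the ``paired_with`` metadata (e.g. a plasma sample
    pointing at its matched serum).  Returns one row per assay with the
    median paired Ct difference (sample minus its partner) and the Wilcoxon
    signed-rank p-value; p is None when fewer than 2 informative pairs exist.
    Unpaired samples are ignored with a warning.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for m in meta:
        if m.sample_id not in matrix.samples or m.paired_with is None:
            continue
        if m.paired_with not in matrix.samples:
            continue
        key = frozenset((m.sample_id, m.paired_with))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((m.sample_id, m.paired_with))
    in_pairs = {s for pair in pairs for s in pair}
    unpaired = sum(1 for m in meta
                   if m.sample_id in matrix.samples
                   and m.sample_id not in in_pairs)
    if unpaired:
        warnings.warn(f"{unpaired} unpaired sample(s) excluded", stacklevel=2)
    if not pairs:
        raise ValueError("no matched pairs found")
    rows = []
    for assay in assays:
        a = np.array([matrix.value(assay, s1) for s1, _ in pairs])
        b = np.array([matrix.value(assay, s2) for _, s2 in pairs])
        diffs = a - b
        informative = diffs[diffs != 0]
        if len(pairs) < 2 or len(informative) == 0:
            p = None if len(pairs) < 2 else 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        rows.append({
            "assay": assay,
            "n_pairs": len(pairs),
            "median_diff": float(np.median(diffs)),
            "p_value": p,
        })
    return pd.DataFrame(rows)
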