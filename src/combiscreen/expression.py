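"""Expression computations: DEG filtering, heatmap gene selection, UPGMA
clustering, and 2^-ΔΔCt relative quantification with error propagation.

Differential expression uses a two-rule filter on gene-level intensities:

1. |log2 fold change| >= 1 and p < 0.05 (Welch two-sample t-test on log2
   intensities; the proprietary array-platform error model originally used
   for these p-values is not reproducible, so an unequal-variance location
   test stands in for it — see the methods note);
2. when the log2 ratio is undefined (a group with no usable signal), the
   gene is still called if the group-mean intensity difference is >= 1000.

Heatmap genes are chosen by per-gene intensity range (max - min across
samples), sorted descending. Clustering is average-linkage (UPGMA)
agglomeration on log2-transformed, gene-mean-centered data.

qPCR relative quantification follows the ddCt scheme: ΔCt = Ct_target -
Ct_reference per group, ΔΔCt = ΔCt_treated - ΔCt_calibrator, fold change =
2^-ΔΔCt, with the ΔΔCt standard deviation propagated in quadrature from the
four per-term standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .simulate import ExpressionTable

__all__ = [
    "DegRecord",
    "FoldChangeResult",
    "LinkageTree",
    "differential_expression",
    "select_heatmap_genes",
    "mean_center",
    "average_linkage_cluster",
    "ddct_fold_change",
]

FC_THRESHOLD = 1.0        # |log2 FC| gate
ALPHA = 0.05              # p-value gate
NA_INTENSITY_CUTOFF = 1000.0  # intensity-difference gate for undefined ratios


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2_fc: float
    p_value: float
    passed_rule: str  # fc_and_p | na_intensity | none


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    ddct: float
    fold_change: float
    propagated_sd: float | None
    fold_interval: tuple[float, float] | None


@dataclass
class LinkageTree:
    """UPGMA merge sequence in scipy linkage encoding, plus leaf labels."""

    merges: np.ndarray            # (n-1) x 4 scipy linkage matrix
    labels: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _log2_safe(values: pd.DataFrame) -> pd.DataFrame:
    """log2 of intensities; non-positive or missing entries become NaN."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = np.log2(values.where(values > 0))
    return out


def differential_expression(
    expr: ExpressionTable,
    group_a: str,
    group_b: str,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    na_intensity_cutoff: float = NA_INTENSITY_CUTOFF,
    adjust: bool = False,
) -> pd.DataFrame:
    """Apply the two-rule DEG filter to groups ``group_b`` vs ``group_a``.

    log2_fc is the mean log2 intensity of ``group_b`` minus that of
    ``group_a``. ``adjust=True`` replaces raw p-values with
    Benjamini–Hochberg adjusted ones before gating. Returns one row per
    gene with the rule (if any) that selected it.
    """
    for g in (group_a, group_b):
        if g not in set(expr.groups):
            raise ValueError(f"group {g!r} not present in the expression table")
    cols_a = expr.groups.index[expr.groups == group_a]
    cols_b = expr.groups.index[expr.groups == group_b]
    log2 = _log2_safe(expr.values)
    la, lb = log2[cols_a], log2[cols_b]
    mean_a, mean_b = la.mean(axis=1), lb.mean(axis=1)
    log2_fc = mean_b - mean_a

    p = pd.Series(np.nan, index=expr.values.index)
    if len(cols_a) >= 2 and len(cols_b) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(
                lb.to_numpy(), la.to_numpy(), axis=1, equal_var=False, nan_policy="omit"
            )
        p[:] = res.pvalue
    else:
        warnings.warn(
            "a group has fewer than 2 samples; the p-value rule is skipped",
            stacklevel=2,
        )
    if adjust:
        valid = p.notna()
        p.loc[valid] = stats.false_discovery_control(p[valid], method="bh")

    # group-mean intensities for the undefined-ratio rule; a group with no
    # usable signal contributes 0
    int_a = expr.values[cols_a].mean(axis=1).fillna(0.0)
    int_b = expr.values[cols_b].mean(axis=1).fillna(0.0)
    intensity_diff = (int_b - int_a).abs()
    ratio_undefined = mean_a.isna() | mean_b.isna()

    rule1 = (~ratio_undefined) & (log2_fc.abs() >= fc_threshold) & (p < alpha)
    rule2 = ratio_undefined & (intensity_diff >= na_intensity_cutoff)
    passed = np.where(rule1, "fc_and_p", np.where(rule2, "na_intensity", "none"))
    return pd.DataFrame(
        {
            "gene": expr.values.index,
            "log2_fc": log2_fc.to_numpy(),
            "p_value": p.to_numpy(),
            "intensity_diff": intensity_diff.to_numpy(),
            "passed_rule": passed,
        }
    ).reset_index(drop=True)


def select_heatmap_genes(values: pd.DataFrame, k: int) -> list[str]:
    """Top-k genes by intensity range (max - min across samples), descending.

    Ties are broken lexicographically by gene id; constant genes (range 0)
    are only reached after every varying gene.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(values):
        raise ValueError(f"k={k} exceeds the {len(values)} genes available")
    ranges = values.max(axis=1) - values.min(axis=1)
    order = (
        pd.DataFrame({"range": ranges})
        .sort_index()  # lexicographic tie-break
        .sort_values("range", ascending=False, kind="mergesort")
    )
    return order.index[:k].tolist()


def mean_center(values: pd.DataFrame, log2_transform: bool = True) -> pd.DataFrame:
    """Row-center each gene to mean 0 (after log2 transformation by default)."""
    mat = _log2_safe(values) if log2_transform else values.astype(float)
    return mat.sub(mat.mean(axis=1), axis=0)


def average_linkage_cluster(centered: pd.DataFrame, distance: str = "euclidean") -> LinkageTree:
    """UPGMA (average-linkage) agglomeration of gene rows.

    ``distance`` is ``"euclidean"`` or ``"correlation"`` (1 - Pearson).
    Constant rows, whose correlation distance is undefined, are dropped with
    a flag when the correlation metric is used.
    """
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance {distance!r}")
    mat = centered.astype(float)
    dropped: list[str] = []
    if distance == "correlation":
        degenerate = mat.std(axis=1, ddof=0) == 0
        dropped = mat.index[degenerate].tolist()
        mat = mat.loc[~degenerate]
    if len(mat) < 2:
        raise ValueError("clustering needs at least 2 (non-degenerate) genes")
    d = pdist(mat.to_numpy(), metric=distance)
    merges = hierarchy.linkage(d, method="average")
    return LinkageTree(merges=merges, labels=mat.index.tolist(), dropped=dropped)


def _group_stats(ct: pd.DataFrame, gene: str, group: str) -> tuple[float, float, int]:
    sub = ct.loc[(ct["gene"] == gene) & (ct["group"] == group), "ct"].dropna()
    if sub.empty:
        raise ValueError(f"no Ct values for gene {gene!r} in group {group!r}")
    n = len(sub)
    sd = float(sub.std(ddof=1)) if n >= 2 else float("nan")
    return float(sub.mean()), sd, n


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_group: str,
    treated_group: str,
) -> FoldChangeResult:
    """2^-ΔΔCt fold change of ``target`` vs ``reference``, treated vs calibrator.

    ``ct`` is long-format with columns (gene, group, replicate, ct). The
    ΔΔCt standard deviation is the quadrature sum of the four standard
    errors (target and reference in each group); with single replicates
    anywhere, only the point estimate is returned. The fold interval is
    [2^-(ΔΔCt+sd), 2^-(ΔΔCt-sd)].
    """
    for col in ("gene", "group", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table is missing column {col!r}")
    if reference not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference!r} absent from the Ct table")
    stats_ = {
        (g, grp): _group_stats(ct, g, grp)
        for g in (target, reference)
        for grp in (calibrator_group, treated_group)
    }
    d_treat = stats_[(target, treated_group)][0] - stats_[(reference, treated_group)][0]
    d_cal = stats_[(target, calibrator_group)][0] - stats_[(reference, calibrator_group)][0]
    ddct = d_treat - d_cal
    fold = 2.0 ** (-ddct)

    ses = []
    for (g, grp), (_, sd, n) in stats_.items():
        if n < 2 or np.isnan(sd):
            ses = None
            break
        ses.append(sd / np.sqrt(n))
    if ses is None:
        warnings.warn("single replicate present: propagated sd unavailable", stacklevel=2)
        return FoldChangeResult(target, float(ddct), float(fold), None, None)
    sd_ddct = float(np.sqrt(np.sum(np.square(ses))))
    interval = (2.0 ** (-(ddct + sd_ddct)), 2.0 ** (-(ddct - sd_ddct)))
    return FoldChangeResult(target, float(ddct), float(fold), sd_ddct, interval)
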