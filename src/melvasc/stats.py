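"""Sample-level aggregation, adaptive two-group testing, correlation, ANOVA,
and inflammatory-environment clustering.

The two-group comparison mirrors the common wet-lab convention: each group is
tested for normality (Shapiro-Wilk at alpha = 0.05); if both pass, a Student
t test (paired or unpaired) is used, otherwise the corresponding rank test
(Wilcoxon signed-rank or Mann-Whitney U).  Correlations switch between
Pearson and Spearman on the same criterion.  No multiple-testing correction
is applied; raw p-values are emitted with the chosen test's name so users can
adjust as needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

log = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05

#: Leukocyte density columns of the inflammation matrix.
INFLAMMATION_CLASSES = ("CD8_T", "MACROPHAGE", "B_CELL", "OTHER_CD45")


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    pvalue: float


def _is_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    if np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def compare_groups(
    values_a,
    values_b,
    paired: bool = False,
) -> TestResult:
    """Adaptive two-group comparison (normality-gated t vs rank test)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("insufficient data: each group needs n >= 3")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison needs equal-length groups")
    normal = _is_normal(a) and _is_normal(b)
    if normal:
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t test"
        else:
            res = sps.ttest_ind(a, b)
            name = "t test"
    else:
        if paired:
            diff = a - b
            if np.all(diff == 0):
                return TestResult("wilcoxon signed-rank", 0.0, 1.0)
            res = sps.wilcoxon(a, b)
            name = "wilcoxon signed-rank"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "mann-whitney"
    return TestResult(name, float(res.statistic), float(res.pvalue))


def correlate(x, y) -> CorrelationResult:
    """Pearson when both vectors are normal, Spearman otherwise.

    Missing pairs are deleted pairwise; constant vectors yield an undefined,
    flagged result rather than an error.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("correlation needs n >= 4 after pairwise deletion")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector: correlation undefined")
        return CorrelationResult("undefined", np.nan, np.nan)
    if _is_normal(x) and _is_normal(y):
        r, p = sps.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p))
    r, p = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(r), float(p))


def anova_oneway(groups) -> TestResult:
    """Classical one-way ANOVA over >= 3 groups; 2 groups delegate to
    :func:`compare_groups`."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) == 2:
        return compare_groups(groups[0], groups[1])
    if any(len(g) < 2 for g in groups):
        raise ValueError("degenerate group: each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult("one-way anova", 0.0, 1.0)
    res = sps.f_oneway(*groups)
    return TestResult("one-way anova", float(res.statistic), float(res.pvalue))


def aggregate_samples(
    roi_summaries: pd.DataFrame,
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample means of all numeric per-ROI fields.

    ``manifest`` maps ``roi_id`` to ``sample_id`` (plus any covariates, which
    are carried through).  Missing ROI values are excluded pairwise; an ROI
    absent from the manifest is an error.
    """
    if "roi_id" not in roi_summaries or "roi_id" not in manifest:
        raise ValueError("both tables need a roi_id column")
    unmapped = set(roi_summaries.roi_id) - set(manifest.roi_id)
    if unmapped:
        raise ValueError(f"ROIs not mapped to any sample: {sorted(unmapped)}")
    merged = roi_summaries.merge(manifest, on="roi_id", how="left")
    numeric = merged.select_dtypes(include=[np.number]).columns
    covars = [c for c in manifest.columns
              if c not in ("roi_id", "sample_id") and c not in numeric]
    agg = merged.groupby("sample_id")[list(numeric)].mean()
    agg["n_rois"] = merged.groupby("sample_id")["roi_id"].count()
    if covars:
        first = merged.groupby("sample_id")[covars].first()
        agg = agg.join(first.drop(columns=[c for c in first if c in agg], errors="ignore"))
    return agg.reset_index()


@dataclass
class InflammationClustering:
    scaled: pd.DataFrame          # z-scored density matrix (samples x classes)
    labels: np.ndarray            # ordered 0..k-1 by descending mean CD8 density
    names: dict[int, str]
    order: np.ndarray             # dendrogram leaf order of samples
    constant_columns: list[str]


def inflammatory_subtypes(matrix: pd.DataFrame, k: int = 3) -> InflammationClustering:
    """Cluster samples into inflammatory environments.

    ``matrix`` is samples x leukocyte-class densities.  Each class column is
    z-scored across samples (the heatmap's per-marker scaling; a constant
    column becomes all-zero and is flagged), then samples are joined by
    Ward/Euclidean agglomerative clustering and the tree is cut at ``k``.
    Labels are renumbered by descending within-cluster mean CD8 density so
    that label 0 is always the most T-cell-rich environment.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of samples ({len(matrix)})")
    X = matrix.astype(float).copy()
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        log.warning("constant density columns scaled to zero: %s", constant)
    scaled = X.copy()
    for c in X.columns:
        col = X[c].to_numpy()
        sd = col.std()
        scaled[c] = 0.0 if sd == 0 else (col - col.mean()) / sd

    if k == 1 or len(matrix) == 1:
        labels = np.zeros(len(matrix), dtype=int)
        order = np.arange(len(matrix))
    else:
        Z = linkage(scaled.to_numpy(), method="ward", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
        from scipy.cluster.hierarchy import leaves_list

        order = leaves_list(Z)
        # renumber by descending mean CD8 density (raw scale when available)
        cd8_col = "CD8_T" if "CD8_T" in matrix.columns else matrix.columns[0]
        means = {
            lab: matrix[cd8_col].to_numpy()[raw == lab].mean()
            for lab in np.unique(raw)
        }
        rank = {lab: i for i, lab in enumerate(
            sorted(means, key=means.get, reverse=True))}
        labels = np.array([rank[lab] for lab in raw])

    base_names = {0: "inflamed", 1: "t_cell_rich", 2: "uninflamed"}
    names = {i: base_names.get(i, f"cluster_{i}") for i in np.unique(labels)}
    return InflammationClustering(
        scaled=scaled, labels=labels, names=names, order=order,
        constant_columns=constant,
    )
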