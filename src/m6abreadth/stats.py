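"""Comparison surface: group tests, rank correlations, smoothing export.

Group differences between gene classes (e.g. frequently vs.
occasionally methylated) are summarized as mean ± standard error and
tested with the two-sided Wilcoxon rank-sum test; threshold-free
associations use Spearman correlation against the corrected condition
count or the quantitative breadth. Raw p-values are reported (matching
common practice for these per-feature tests); a Benjamini–Hochberg
column is emitted additionally but does not drive any flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "wilcoxon_compare",
    "spearman_correlate",
    "trim_for_loess",
    "loess_points",
    "build_summary",
]


@dataclass
class GroupComparison:
    feature_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    test_statistic: float
    p_value: float


@dataclass
class CorrelationResult:
    feature_name: str
    predictor: str
    rho: float
    p_value: float
    n_used: int


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[np.isfinite(x)]


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def wilcoxon_compare(
    values_a, values_b, feature_name: str = "", group_a: str = "a", group_b: str = "b"
) -> GroupComparison | None:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two groups.

    Uses the normal approximation with tie correction and reports the
    group means with their standard errors (sd/√n). Returns None (with
    a log entry) when either sample has fewer than 2 finite values.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        logger.info("comparison %r skipped: group sizes %d vs %d", feature_name, len(a), len(b))
        return None
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        feature_name=feature_name,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        se_a=_se(a),
        mean_b=float(np.mean(b)),
        se_b=_se(b),
        test_statistic=float(res.statistic),
        p_value=float(min(max(res.pvalue, np.finfo(float).tiny), 1.0)),
    )


def spearman_correlate(x, y, feature_name: str = "", predictor: str = "") -> CorrelationResult | None:
    """Spearman rank correlation with average-rank ties, pairwise-complete.

    Returns None (logged) with fewer than 3 complete pairs or when
    either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("correlation %r vs %r skipped (n=%d or constant input)", feature_name, predictor, len(x))
        return None
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(
        feature_name=feature_name,
        predictor=predictor,
        rho=float(rho),
        p_value=float(min(max(p, np.finfo(float).tiny), 1.0)),
        n_used=len(x),
    )


def trim_for_loess(table: pd.DataFrame, predictor: str, fraction: float = 0.005) -> pd.DataFrame:
    """Drop the extreme upper tail of the predictor before smoothing.

    Rows strictly above the (1 − fraction) quantile of the predictor are
    removed; they carry high feature-value variance and would skew the
    local regression. ``fraction=0`` is the identity.
    """
    if fraction <= 0:
        return table.copy()
    x = table[predictor]
    cutoff = x.quantile(1.0 - fraction)
    return table[~(x > cutoff)].copy()


def loess_points(
    table: pd.DataFrame, predictor: str, feature: str, frac: float = 0.75, trim: float = 0.005
) -> pd.DataFrame:
    """LOESS-smoothed (predictor, feature) curve for plotting export."""
    sub = trim_for_loess(table[[predictor, feature]].dropna(), predictor, trim)
    if len(sub) < 10:
        return pd.DataFrame(columns=[predictor, feature])
    sm = lowess(sub[feature], sub[predictor], frac=frac, return_sorted=True)
    return pd.DataFrame(sm, columns=[predictor, feature])


def build_summary(
    table: pd.DataFrame,
    feature_cols: list[str],
    class_col: str = "class_label",
    predictors: tuple = ("corrected_conditions", "breadth"),
    group_pairs: tuple = (("freq", "occa"),),
    enrich: pd.DataFrame | None = None,
    export_loess: bool = False,
    trim_fraction: float = 0.005,
) -> dict:
    """Assemble the full comparison report from a joined per-gene table.

    Produces one group comparison per feature per group pair, one
    Spearman correlation per feature per available predictor, and an
    optional motif-enrichment block. Missing values are dropped pairwise
    per test. Raises when the join contributed no usable rows.
    """
    if not len(table):
        raise ValueError("empty joined table: no gene overlap between module outputs")
    comparisons = []
    for a_lab, b_lab in group_pairs:
        ga = table[table[class_col] == a_lab] if class_col in table else table.iloc[0:0]
        gb = table[table[class_col] == b_lab] if class_col in table else table.iloc[0:0]
        for feat in feature_cols:
            if feat not in table.columns:
                continue
            cmp_res = wilcoxon_compare(ga[feat], gb[feat], feat, a_lab, b_lab)
            if cmp_res is not None:
                comparisons.append(cmp_res)
    correlations = []
    for pred in predictors:
        if pred not in table.columns:
            continue
        for feat in feature_cols:
            if feat not in table.columns or feat == pred:
                continue
            corr = spearman_correlate(table[pred], table[feat], feat, pred)
            if corr is not None:
                correlations.append(corr)

    comp_df = pd.DataFrame([c.__dict__ for c in comparisons])
    corr_df = pd.DataFrame([c.__dict__ for c in correlations])
    for df in (comp_df, corr_df):
        if len(df):
            df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    report = {"comparisons": comp_df, "correlations": corr_df}
    if enrich is not None:
        report["motif_enrichment"] = enrich
    if export_loess:
        pieces = []
        for pred in predictors:
            if pred not in table.columns:
                continue
            for feat in feature_cols:
                if feat not in table.columns or feat == pred:
                    continue
                pts = loess_points(table, pred, feat, trim=trim_fraction)
                if len(pts):
                    pts = pts.rename(columns={pred: "predictor_value", feat: "feature_value"})
                    pts.insert(0, "feature_name", feat)
                    pts.insert(0, "predictor", pred)
                    pieces.append(pts)
        report["loess_points"] = (
            pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
        )
    return report
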