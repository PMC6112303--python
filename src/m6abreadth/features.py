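"""Gene-importance feature assembly.

Collects the per-gene features used to contrast frequently and
occasionally methylated genes: protein–protein interaction (PPI) degree,
tissue expression specificity (the tau index), evolutionary-rate
passthroughs (dN/dS, ortholog counts), and miRNA-targeting counts split
by co-expression class.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tau",
    "tau_table",
    "compute_ppi_degree",
    "filter_mirna_evidence",
    "classify_coexpression",
    "count_targeting_mirnas",
    "assemble_feature_table",
]


def compute_tau(expression: Sequence[float] | np.ndarray) -> float:
    """Tissue-specificity index tau of a nonnegative expression profile.

    tau = sum_i (1 - x_i / x_max) / (N - 1); 0 for a perfectly uniform
    profile, 1 for expression restricted to a single context. Undefined
    (NaN) for all-zero profiles or profiles of length < 2. Negative
    entries should not occur and are clipped to 0 with a warning.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        return float("nan")
    if (x < 0).any():
        logger.warning("negative expression values clipped to 0 in tau computation")
        x = np.clip(x, 0.0, None)
    xmax = x.max()
    if xmax <= 0:
        return float("nan")
    return float((1.0 - x / xmax).sum() / (x.size - 1))


def tau_table(atlas: pd.DataFrame) -> pd.Series:
    """Row-wise tau over a gene-by-tissue matrix (genes in the index).

    All-zero genes get NaN and are reported in the log.
    """
    x = atlas.to_numpy(dtype=float)
    x = np.clip(x, 0.0, None)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau[xmax <= 0] = np.nan
    out = pd.Series(tau, index=atlas.index, name="tissue_tau")
    n_undef = int(out.isna().sum())
    if n_undef:
        logger.info("tau undefined for %d all-zero gene(s)", n_undef)
    return out


def compute_ppi_degree(edges: pd.DataFrame, physical_types: Iterable[str] = ("physical",)) -> pd.Series:
    """Distinct-partner degree over physical protein–protein edges.

    ``edges`` needs columns gene_a, gene_b and, optionally,
    interaction_type; genetic / protein–RNA interaction rows are
    discarded before counting. Self-loops and duplicate edges collapse.
    """
    df = edges
    if "interaction_type" in df.columns:
        df = df[df["interaction_type"].isin(set(physical_types))]
    df = df[df["gene_a"] != df["gene_b"]]
    pairs = pd.DataFrame(
        np.sort(df[["gene_a", "gene_b"]].to_numpy(dtype=object), axis=1),
        columns=["u", "v"],
    ).drop_duplicates()
    deg = pd.concat([pairs["u"], pairs["v"]]).value_counts()
    deg.name = "ppi_degree"
    deg.index.name = "gene_id"
    return deg.sort_index()


def filter_mirna_evidence(records: pd.DataFrame) -> pd.DataFrame:
    """Keep miRNA–target pairs with >=1 strong or >=3 weak evidence records."""
    keep = (records["n_strong"] >= 1) | (records["n_weak"] >= 3)
    return records[keep].copy()


def mutual_rank(pct_mirna: np.ndarray | float, pct_gene: np.ndarray | float):
    """Geometric mean of the miRNA-side and gene-side co-expression percentiles."""
    return np.sqrt(np.asarray(pct_mirna, dtype=float) * np.asarray(pct_gene, dtype=float))


def classify_coexpression(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each miRNA–target pair a co-expression class.

    Positive correlation with mutual rank < 0.5 -> "positive"; negative
    correlation with mutual rank > 0.5 -> "negative"; anything else
    (including boundary values corr == 0 or MR == 0.5) stays
    "unclassified". The mutual rank is recomputed from the two
    percentiles so the geometric-mean invariant always holds.
    """
    out = records.copy()
    mr = mutual_rank(out["pct_mirna"].to_numpy(), out["pct_gene"].to_numpy())
    out["mutual_rank"] = mr
    corr = out["correlation"].to_numpy(dtype=float)
    cls = np.full(len(out), "unclassified", dtype=object)
    cls[(corr > 0) & (mr < 0.5)] = "positive"
    cls[(corr < 0) & (mr > 0.5)] = "negative"
    out["coexpr_class"] = cls
    return out


def count_targeting_mirnas(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of distinct targeting miRNAs, total and per class.

    Expects evidence-filtered records with a ``coexpr_class`` column
    (see :func:`classify_coexpression`).
    """
    total = records.groupby("gene_id")["mirna_id"].nunique()
    pos = (
        records[records["coexpr_class"] == "positive"].groupby("gene_id")["mirna_id"].nunique()
    )
    neg = (
        records[records["coexpr_class"] == "negative"].groupby("gene_id")["mirna_id"].nunique()
    )
    out = pd.DataFrame(
        {
            "n_mirnas_total": total,
            "n_mirnas_pos": pos.reindex(total.index, fill_value=0),
            "n_mirnas_neg": neg.reindex(total.index, fill_value=0),
        }
    ).astype(int)
    out.index.name = "gene_id"
    return out


def assemble_feature_table(*sources: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Outer-join per-gene feature blocks keyed by gene_id.

    Missing blocks stay NaN. A duplicate gene_id within a single source
    is a data error and is rejected. The join is order-invariant (the
    output is sorted by gene_id and by column name within each block's
    original order).
    """
    frames = []
    for src in sources:
        df = src.to_frame() if isinstance(src, pd.Series) else src
        if df.index.name != "gene_id":
            if "gene_id" in df.columns:
                df = df.set_index("gene_id")
            else:
                raise ValueError("each feature source must be keyed by gene_id")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene_id within one feature source: {dupes}")
        frames.append(df)
    out = pd.concat(frames, axis=1, join="outer")
    out = out[sorted(out.columns)].sort_index()
    out.index.name = "gene_id"
    return out
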