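"""Gene-level summaries of m6A methylation across conditions.

Takes per-condition MeRIP-seq peak profiles and produces, for every
gene: the raw number of conditions with at least one peak, the corrected
condition count (raw divided by the number of profile-covered cell
types where the gene has baseline expression, TPM > 0.5), a class label
(frequently / occasionally / intermediately methylated, never
methylated, or unexpressed), and a quantitative regulation breadth
(1 - tau over per-condition log-transformed total peak-enrichment
scores).

Coordinates follow the BED convention (0-based, half-open); an overlap
means an intersection of at least one base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

from .config import CORE_COMPONENTS
from .features import compute_tau, tau_table

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionProfile",
    "filter_perturbed_profiles",
    "merge_replicates",
    "map_peaks_to_genes",
    "count_corrected_conditions",
    "classify_genes",
    "identify_none_genes",
    "compute_breadth",
    "build_gene_summary",
]

PEAK_COLUMNS = ["contig", "start", "end", "strand", "score"]


@dataclass
class ConditionProfile:
    """One replicate of one m6A profiling condition.

    ``peaks`` holds BED-like records (contig, start, end, strand, score)
    with positive enrichment scores. ``perturbed_components`` lists any
    methylation machinery genes (writers/erasers) whose expression was
    experimentally perturbed in this profile.
    """

    condition_id: str
    cell_type: str
    replicate_id: str
    perturbed_components: frozenset = field(default_factory=frozenset)
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self) -> None:
        if not self.condition_id:
            raise ValueError("condition_id must be nonempty")
        p = self.peaks
        if len(p):
            if not (p["start"] < p["end"]).all():
                raise ValueError(f"profile {self.condition_id}/{self.replicate_id}: peak with start >= end")
            if not (p["score"] > 0).all():
                raise ValueError(f"profile {self.condition_id}/{self.replicate_id}: non-positive enrichment score")


def filter_perturbed_profiles(profiles: list[ConditionProfile]) -> list[ConditionProfile]:
    """Drop profiles in which any m6A core component was perturbed.

    The core set comprises the writers METTL3, METTL14 and WTAP and the
    erasers ALKBH5 and FTO; perturbation of readers (e.g. YTHDF2) does
    not disqualify a profile.
    """
    kept = []
    for p in profiles:
        hit = set(p.perturbed_components) & CORE_COMPONENTS
        if hit:
            logger.info(
                "discarding profile %s/%s: perturbed core component(s) %s",
                p.condition_id, p.replicate_id, ",".join(sorted(hit)),
            )
        else:
            kept.append(p)
    logger.info("retained %d of %d profiles after perturbation filter", len(kept), len(profiles))
    return kept


def _union_intervals(peaks: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping intervals per (contig, strand) into their union."""
    if not len(peaks):
        return peaks.loc[:, ["contig", "start", "end", "strand"]].copy()
    out = []
    for (contig, strand), grp in peaks.groupby(["contig", "strand"], sort=True):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        running_end = np.maximum.accumulate(ends)
        new_block = np.ones(len(g), dtype=bool)
        new_block[1:] = starts[1:] >= running_end[:-1]
        block = np.cumsum(new_block) - 1
        merged = pd.DataFrame(
            {
                "contig": contig,
                "start": pd.Series(starts).groupby(block).min().to_numpy(),
                "end": pd.Series(ends).groupby(block).max().to_numpy(),
                "strand": strand,
            }
        )
        out.append(merged)
    return pd.concat(out, ignore_index=True)


def merge_replicates(profiles: list[ConditionProfile]) -> dict[str, pd.DataFrame]:
    """Combine the modification sites of a condition's replicates.

    Binary mode: the per-condition site set is the interval union of all
    replicate peaks, so duplicated or overlapping sites collapse into
    one logical site. Conditions with no replicates are excluded with a
    warning. Quantitative scores are handled separately by
    :func:`compute_breadth`.
    """
    by_condition: dict[str, list[pd.DataFrame]] = {}
    for p in profiles:
        by_condition.setdefault(p.condition_id, []).append(p.peaks)
    merged = {}
    for cond, frames in sorted(by_condition.items()):
        nonempty = [f for f in frames if len(f)]
        if not nonempty:
            merged[cond] = _union_intervals(pd.DataFrame(columns=PEAK_COLUMNS))
            continue
        merged[cond] = _union_intervals(pd.concat(nonempty, ignore_index=True))
    return merged


def _overlap_join(peaks: pd.DataFrame, genes: pd.DataFrame, stranded: bool) -> pd.DataFrame:
    """Overlap-join peak rows against transcript intervals.

    ``genes`` has one row per transcript: gene_id, transcript_id,
    contig, start, end, strand. Returns the peak rows annotated with
    gene_id/transcript_id, one output row per overlapping pair. Peaks on
    unknown contigs are skipped with a warning. Peaks with strand "."
    match both strands even in stranded mode.
    """
    known = set(genes["contig"].unique())
    unknown = set(peaks["contig"].unique()) - known
    if unknown:
        n_skip = int(peaks["contig"].isin(unknown).sum())
        logger.warning("skipping %d peak(s) on unknown contig(s): %s", n_skip, sorted(unknown))
        peaks = peaks[~peaks["contig"].isin(unknown)]
    if not len(peaks) or not len(genes):
        return pd.DataFrame(columns=list(peaks.columns) + ["gene_id", "transcript_id"])

    left = peaks.reset_index(drop=True).rename(
        columns={"contig": "Chromosome", "start": "Start", "end": "End", "strand": "peak_strand"}
    )
    right = genes.rename(
        columns={"contig": "Chromosome", "start": "Start", "end": "End", "strand": "gene_strand"}
    )
    joined = pr.PyRanges(left).join(pr.PyRanges(right)).df
    if not len(joined):
        return pd.DataFrame(columns=list(peaks.columns) + ["gene_id", "transcript_id"])
    if stranded:
        ok = (joined["peak_strand"] == joined["gene_strand"]) | (joined["peak_strand"] == ".")
        joined = joined[ok]
    out = joined.rename(
        columns={"Chromosome": "contig", "Start": "start", "End": "end", "peak_strand": "strand"}
    )
    return out[list(peaks.columns) + ["gene_id", "transcript_id"]].reset_index(drop=True)


def map_peaks_to_genes(
    merged: dict[str, pd.DataFrame], genes: pd.DataFrame, stranded: bool = True
) -> pd.DataFrame:
    """Gene-by-condition methylation incidence.

    A gene counts as methylated under a condition iff at least one
    merged peak overlaps at least one of its transcripts by >= 1 base
    (on the matching strand unless ``stranded=False``); the number of
    peaks within the gene is irrelevant — each condition contributes at
    most 1. Returns the unique (gene_id, condition_id) pairs.
    """
    rows = []
    for cond, peaks in merged.items():
        hit = _overlap_join(peaks, genes, stranded)
        if len(hit):
            for g in hit["gene_id"].unique():
                rows.append((g, cond))
    out = pd.DataFrame(rows, columns=["gene_id", "condition_id"]).drop_duplicates()
    return out.sort_values(["gene_id", "condition_id"]).reset_index(drop=True)


def _n_expressed_covered(
    atlas: pd.DataFrame, covered_celltypes: list[str], tpm_cutoff: float
) -> pd.Series:
    missing = [c for c in covered_celltypes if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas lacks covered cell type column(s): {missing}")
    sub = atlas[covered_celltypes]
    return (sub > tpm_cutoff).sum(axis=1).rename("n_expressed_covered_celltypes")


def count_corrected_conditions(
    incidence: pd.DataFrame,
    atlas: pd.DataFrame,
    covered_celltypes: list[str],
    tpm_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Correct raw condition counts by baseline-expression breadth.

    ``corrected = n_conditions_regulated / n_expressed_covered_celltypes``
    where the denominator counts profile-covered cell types with
    TPM strictly greater than ``tpm_cutoff``. Genes absent from the
    atlas, or expressed in none of the covered cell types, get an
    undefined (NaN) corrected count and are later labeled unexpressed.
    """
    raw = incidence.groupby("gene_id")["condition_id"].nunique().rename("n_conditions_regulated")
    universe = raw.index.union(atlas.index)
    n_expr = _n_expressed_covered(atlas, covered_celltypes, tpm_cutoff)
    out = pd.DataFrame(index=universe)
    out.index.name = "gene_id"
    out["n_conditions_regulated"] = raw.reindex(universe, fill_value=0).astype(int)
    out["in_atlas"] = out.index.isin(atlas.index)
    out["n_expressed_covered_celltypes"] = n_expr.reindex(universe, fill_value=0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = out["n_conditions_regulated"] / out["n_expressed_covered_celltypes"]
    corrected[out["n_expressed_covered_celltypes"] == 0] = np.nan
    out["corrected_conditions"] = corrected
    return out


def classify_genes(
    counts: pd.DataFrame, freq_cutoff: float = 3.5, occa_cutoff: float = 1.5
) -> pd.Series:
    """Label genes by corrected condition count.

    corrected > freq_cutoff -> "freq"; 0 < corrected <= occa_cutoff ->
    "occa"; in between -> "intermediate". Genes with zero methylated
    conditions become "none" if expressed in >= 1 covered cell type and
    "unexpressed" otherwise; genes with methylation but no expression
    evidence are "unexpressed" (the correction is meaningless there).
    """
    corrected = counts["corrected_conditions"]
    raw = counts["n_conditions_regulated"]
    n_expr = counts["n_expressed_covered_celltypes"]
    label = pd.Series("intermediate", index=counts.index, dtype=object, name="class_label")
    label[corrected > freq_cutoff] = "freq"
    label[(corrected > 0) & (corrected <= occa_cutoff)] = "occa"
    label[(raw == 0) & (n_expr > 0)] = "none"
    label[n_expr == 0] = "unexpressed"
    return label


def identify_none_genes(
    incidence: pd.DataFrame,
    atlas: pd.DataFrame,
    covered_celltypes: list[str],
    tpm_cutoff: float = 0.5,
) -> pd.Index:
    """Expressed-but-never-methylated genes.

    A gene qualifies when it has baseline expression (TPM > cutoff) in at
    least one profile-covered cell type yet zero peaks across all
    retained conditions.
    """
    n_expr = _n_expressed_covered(atlas, covered_celltypes, tpm_cutoff)
    expressed = n_expr[n_expr > 0].index
    methylated = set(incidence["gene_id"].unique())
    return pd.Index([g for g in expressed if g not in methylated], name="gene_id")


def compute_breadth(
    profiles: list[ConditionProfile],
    genes: pd.DataFrame,
    stranded: bool = True,
    return_scores: bool = False,
):
    """Quantitative m6A regulation breadth, 1 - tau over condition scores.

    Per condition and replicate, peak enrichment scores are summed along
    each transcript; for multi-transcript genes only the maximum
    transcript total is retained; replicate totals are averaged and then
    log10(x + 1)-transformed (so conditions without peaks contribute 0
    and stay 0). The resulting per-gene vector of one value per retained
    condition is summarized by the specificity index tau; breadth =
    1 - tau lies in [0, 1], higher meaning more broadly methylated.
    Genes with zero score in every condition get NaN.
    """
    conditions = sorted({p.condition_id for p in profiles})
    frames = []
    for p in profiles:
        if not len(p.peaks):
            continue
        df = p.peaks.copy()
        df["condition_id"] = p.condition_id
        df["replicate_id"] = p.replicate_id
        frames.append(df)
    if not frames:
        empty = pd.Series(dtype=float, name="breadth")
        return (empty, pd.DataFrame()) if return_scores else empty
    peaks = pd.concat(frames, ignore_index=True)
    hit = _overlap_join(peaks, genes, stranded)
    # transcript totals -> gene max per replicate -> replicate mean
    per_tx = hit.groupby(["gene_id", "condition_id", "replicate_id", "transcript_id"])["score"].sum()
    per_rep = per_tx.groupby(["gene_id", "condition_id", "replicate_id"]).max()
    per_cond = per_rep.groupby(["gene_id", "condition_id"]).mean()
    mat = per_cond.unstack("condition_id").reindex(columns=conditions).fillna(0.0)
    mat = np.log10(mat + 1.0)
    breadth = 1.0 - tau_table(mat)
    breadth.name = "breadth"
    return (breadth, mat) if return_scores else breadth


def build_gene_summary(
    profiles: list[ConditionProfile],
    genes: pd.DataFrame,
    atlas: pd.DataFrame,
    covered_celltypes: list[str],
    tpm_cutoff: float = 0.5,
    freq_cutoff: float = 3.5,
    occa_cutoff: float = 1.5,
    stranded: bool = True,
) -> pd.DataFrame:
    """Full per-gene summary: counts, corrected counts, class and breadth."""
    retained = filter_perturbed_profiles(profiles)
    merged = merge_replicates(retained)
    incidence = map_peaks_to_genes(merged, genes, stranded=stranded)
    counts = count_corrected_conditions(incidence, atlas, covered_celltypes, tpm_cutoff)
    counts["class_label"] = classify_genes(counts, freq_cutoff, occa_cutoff)
    breadth = compute_breadth(retained, genes, stranded=stranded)
    counts["breadth"] = breadth.reindex(counts.index)
    return counts.drop(columns=["in_atlas"])
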