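"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV; peak files are BED6 whose score
column carries the quantitative enrichment score; gene models are BED12
(single- or multi-block transcripts are both treated as their whole
span) with the name field ``gene_id|transcript_id``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .m6a import ConditionProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_peak_profiles",
    "read_gene_models",
    "read_atlas",
    "read_gene_list",
    "apply_alias_map",
    "write_tsv",
    "write_report_json",
]

_BED6 = ["contig", "start", "end", "name", "score", "strand"]


def read_peak_profiles(peaks_dir: str | Path, meta_path: str | Path) -> list[ConditionProfile]:
    """Load per-condition peak BED files described by a metadata TSV.

    The metadata needs columns condition_id, cell_type, replicate_id and
    perturbed_components (comma-separated, possibly empty); the peak
    file for a row is ``<condition_id>_<replicate_id>.bed`` in
    ``peaks_dir``.
    """
    peaks_dir = Path(peaks_dir)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    profiles = []
    for _, row in meta.iterrows():
        path = peaks_dir / f"{row['condition_id']}_{row['replicate_id']}.bed"
        if not path.exists():
            raise FileNotFoundError(f"peak file missing for metadata row: {path}")
        peaks = pd.read_csv(path, sep="\t", header=None, names=_BED6)
        peaks = peaks.drop(columns=["name"])
        perturbed = frozenset(x for x in row["perturbed_components"].split(",") if x)
        profiles.append(
            ConditionProfile(
                condition_id=row["condition_id"],
                cell_type=row["cell_type"],
                replicate_id=row["replicate_id"],
                perturbed_components=perturbed,
                peaks=peaks[["contig", "start", "end", "strand", "score"]],
            )
        )
    logger.info("loaded %d profiles from %s", len(profiles), peaks_dir)
    return profiles


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene models from BED12 (name = ``gene_id|transcript_id``).

    Each transcript becomes one interval row; the transcript's full span
    is used (exon blocks are not projected out).
    """
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    n_cols = first.shape[1]
    names = _BED6 + [f"c{i}" for i in range(6, n_cols)]
    bed = pd.read_csv(path, sep="\t", header=None, names=names)
    split = bed["name"].str.split("|", n=1, expand=True)
    if split.shape[1] < 2 or split[1].isna().any():
        raise ValueError("gene-model BED name field must be 'gene_id|transcript_id'")
    out = pd.DataFrame(
        {
            "gene_id": split[0],
            "transcript_id": split[1],
            "contig": bed["contig"],
            "start": bed["start"],
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )
    if not (out["start"] < out["end"]).all():
        raise ValueError("gene-model BED contains an interval with start >= end")
    return out


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t", index_col=0)
    atlas.index.name = "gene_id"
    return atlas


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def apply_alias_map(df: pd.DataFrame, map_path: str | Path, column: str = "gene_id") -> pd.DataFrame:
    """Translate identifiers via a two-column alias->gene_id TSV.

    Rows whose identifier has no mapping are dropped, with the count
    logged (mirrors standard ID-harmonization before joining sources).
    """
    amap = pd.read_csv(map_path, sep="\t", header=None, names=["alias", "gene_id_mapped"], dtype=str)
    lookup = dict(zip(amap["alias"], amap["gene_id_mapped"]))
    mapped = df[column].map(lookup)
    n_drop = int(mapped.isna().sum())
    if n_drop:
        logger.info("alias map: dropped %d unmapped record(s)", n_drop)
    out = df[mapped.notna()].copy()
    out[column] = mapped[mapped.notna()]
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.replace({np.nan: None}).to_json(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    out = {k: _jsonable(v) for k, v in report.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, allow_nan=False, default=_jsonable)
        fh.write("\n")
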