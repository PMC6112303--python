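"""End-to-end orchestration: synthesize (optional) → compile → features
→ topology → motifs → compare.

Each stage writes its outputs under the run directory and the run
finishes with a manifest recording the config, the seed, the stage
sequence and the SHA-256 of every output file, so reruns are verifiably
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import features as ft
from . import io as mio
from . import motifs as mo
from . import stats as st
from . import synthetic as syn
from . import topology as tp
from .config import RunConfig
from .m6a import build_gene_summary

logger = logging.getLogger(__name__)

__all__ = ["run_all"]

#: feature columns entering the comparison surface, in emission order
FEATURE_COLUMNS = [
    "dnds",
    "n_orthologs",
    "ppi_degree",
    "tissue_tau",
    "n_mirnas_total",
    "n_mirnas_pos",
    "n_mirnas_neg",
]
TOPO_COLUMNS = [
    "deg_directed_total",
    "deg_act_in",
    "deg_act_out",
    "deg_rep_in",
    "deg_rep_out",
    "betweenness",
    "closeness",
    "eigenvector",
    "transitivity",
    "ppi_only_degree",
    "partner_mean_ppi_degree",
    "relative_level",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_path(p: str | None, name: str) -> Path:
    if p is None:
        raise ValueError(f"run config: missing input path {name!r} (and no synthetic block)")
    path = Path(p)
    if not path.exists():
        raise FileNotFoundError(f"run config: {name} path does not exist: {path}")
    return path


def run_all(config: RunConfig) -> dict:
    """Execute every pipeline stage in order and return the run manifest.

    With a ``synthetic`` config block, stage 1 generates and writes the
    fixture bundle and the remaining stages consume those files through
    the ordinary readers (so the synthetic path exercises the same I/O
    as a real-data run). Any stage failure propagates with the stage
    named in the log.
    """
    config = replace(config)  # work on a shallow copy; stages fill in paths
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    try:
        if config.synthetic is not None:
            stage = "synthesize"
            cfg = config.synthetic
            fixdir = outdir / "fixtures"
            syn.write_fixture_bundle(syn.generate_all(cfg), fixdir)
            config.peaks_dir = str(fixdir / "peaks")
            config.meta_path = str(fixdir / "meta.tsv")
            config.atlas_path = str(fixdir / "expression.tsv")
            config.genes_path = str(fixdir / "genes.bed")
            config.network_path = str(fixdir / "network.tsv")
            config.receptors_path = str(fixdir / "receptors.txt")
            config.tfs_path = str(fixdir / "tfs.txt")
            config.ppi_path = str(fixdir / "ppi.tsv")
            config.evo_path = str(fixdir / "evo.tsv")
            config.mirna_path = str(fixdir / "mirna.tsv")
            covered = syn.covered_celltypes(cfg)
            stages.append(stage)
        else:
            covered = None

        stage = "compile"
        profiles = mio.read_peak_profiles(
            _require_path(config.peaks_dir, "peaks_dir"), _require_path(config.meta_path, "meta_path")
        )
        genes = mio.read_gene_models(_require_path(config.genes_path, "genes_path"))
        atlas = mio.read_atlas(_require_path(config.atlas_path, "atlas_path"))
        if covered is None:
            covered = sorted({p.cell_type for p in profiles if p.cell_type in atlas.columns})
        summary = build_gene_summary(
            profiles,
            genes,
            atlas,
            covered,
            tpm_cutoff=config.tpm_cutoff,
            freq_cutoff=config.freq_cutoff,
            occa_cutoff=config.occa_cutoff,
            stranded=not config.unstranded,
        )
        mio.write_tsv(summary, outdir / "summary.tsv")
        stages.append(stage)

        stage = "features"
        ppi_edges = pd.read_csv(_require_path(config.ppi_path, "ppi_path"), sep="\t", dtype={"gene_a": str, "gene_b": str})
        evo = pd.read_csv(_require_path(config.evo_path, "evo_path"), sep="\t", index_col=0)
        mirna = pd.read_csv(_require_path(config.mirna_path, "mirna_path"), sep="\t")
        deg = ft.compute_ppi_degree(ppi_edges)
        tau = ft.tau_table(atlas)
        mir = ft.count_targeting_mirnas(ft.classify_coexpression(ft.filter_mirna_evidence(mirna)))
        feat = ft.assemble_feature_table(deg, tau, evo, mir)
        feat["ppi_degree"] = feat["ppi_degree"].fillna(0).astype(int)
        for c in ("n_mirnas_total", "n_mirnas_pos", "n_mirnas_neg"):
            feat[c] = feat[c].fillna(0).astype(int)
        mio.write_tsv(feat, outdir / "features.tsv")
        stages.append(stage)

        stage = "topology"
        net = tp.load_network(
            _require_path(config.network_path, "network_path"),
            _require_path(config.receptors_path, "receptors_path"),
            _require_path(config.tfs_path, "tfs_path"),
        )
        topo = tp.compute_node_topology(net, effector_mode=config.effector_mode)
        mio.write_tsv(topo, outdir / "topology.tsv")
        stages.append(stage)

        stage = "motifs"
        instances = mo.enumerate_motifs(net)
        occurrence = mo.per_gene_occurrence(instances, universe=net.nodes)
        freq_genes = set(summary.index[summary["class_label"] == "freq"]) & net.nodes
        if freq_genes and len(occurrence.columns):
            enrich = mo.resampling_test(
                occurrence,
                sorted(freq_genes),
                universe=net.nodes,
                n_resamples=config.n_resamples,
                seed=config.seed,
            )
        else:
            logger.warning("motif stage: no frequently-methylated genes on the network, skipping test")
            enrich = pd.DataFrame(
                columns=["observed_occurrence", "n_resamples", "n_trials_observed_greater", "empirical_p", "significant"]
            )
        mio.write_tsv(enrich, outdir / "motif_enrichment.tsv")
        stages.append(stage)

        stage = "compare"
        table = summary.join(feat, how="outer").join(topo, how="outer")
        feature_cols = FEATURE_COLUMNS + [c for c in TOPO_COLUMNS if c in table.columns]
        report = st.build_summary(
            table,
            feature_cols,
            enrich=enrich,
            export_loess=True,
            trim_fraction=config.trim_fraction,
        )
        mio.write_tsv(report["comparisons"], outdir / "comparisons.tsv", index=False)
        mio.write_tsv(report["correlations"], outdir / "correlations.tsv", index=False)
        if "loess_points" in report and len(report["loess_points"]):
            mio.write_tsv(report["loess_points"], outdir / "loess_points.tsv", index=False)
        mio.write_report_json(
            {k: v for k, v in report.items() if k != "loess_points"}, outdir / "report.json"
        )
        stages.append(stage)
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        raise

    files = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "run_manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": stages,
        "files": {f: _sha256(outdir / f) for f in files},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d stages, %d files", len(stages), len(files))
    return manifest
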