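"""Seeded synthetic study-condition generator.

Emits schema-faithful stand-ins for every pipeline input — per-condition
methylation peak profiles, a gene-by-tissue expression atlas, a typed
signed signaling network, a binary PPI edge list, per-gene evolutionary
features and a miRNA–target table — with planted statistical structure
so downstream estimates can be validated by parameter recovery.

The planted structure hangs off one latent "regulation breadth" variate
per gene, uniform on (0, 1). Rank correlations between breadth and each
emitted feature are induced through a Gaussian copula whose Pearson
parameter is chosen so the Spearman correlation matches the configured
target exactly in expectation (r = 2 sin(pi * rho_s / 6)). Peak presence
per condition is Bernoulli with probability increasing linearly in
breadth, so emitted condition counts are monotone in breadth in
expectation.

Everything is a pure function of the :class:`~m6abreadth.config.SyntheticConfig`,
including its seed: re-running with the same config reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import CORE_COMPONENTS, SyntheticConfig
from .m6a import ConditionProfile
from .motifs import MotifInstance
from .topology import SignalingNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "FixtureBundle",
    "gene_ids",
    "tissue_names",
    "covered_celltypes",
    "condition_ids",
    "generate_gene_models",
    "generate_peak_profiles",
    "generate_expression_atlas",
    "generate_signaling_network",
    "generate_ppi_network",
    "generate_evo_features",
    "generate_mirna_targets",
    "generate_all",
    "write_fixture_bundle",
]

# independent deterministic substreams per generator stage
_STREAMS = {
    "latent": 0, "peaks": 1, "atlas": 2, "network": 3,
    "ppi": 4, "evo": 5, "mirna": 6,
}

_MOTIF_TEMPLATES = {
    # class -> (n_nodes, edge sign sequence in role/cycle order)
    "CFF": (3, ("+", "+", "+")),
    "IFF": (3, ("+", "+", "-")),
    "PFB": (2, ("+", "+")),
    "NFB": (2, ("+", "-")),
}


@dataclass
class GroundTruth:
    """Planted quantities the pipeline should recover."""

    latent_breadth: pd.Series
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_motifs: list = field(default_factory=list)
    coexpr_truth: pd.DataFrame | None = None


def _rng(cfg: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stage]])


def gene_ids(cfg: SyntheticConfig) -> list[str]:
    width = max(5, len(str(cfg.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def tissue_names(cfg: SyntheticConfig) -> list[str]:
    return [f"tissue_{i:02d}" for i in range(1, cfg.n_tissues + 1)]


def covered_celltypes(cfg: SyntheticConfig) -> list[str]:
    """Tissues flagged as covered by the methylation profiling studies."""
    return tissue_names(cfg)[: cfg.n_cell_types]


def condition_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"cond{i:02d}" for i in range(1, cfg.n_conditions + 1)]


def _latents(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Latent breadth and copula-coupled feature normals, one draw per gene.

    Returns standard-normal scores; ``breadth`` is the uniform latent
    breadth itself. Feature scores share the configured Spearman target
    with breadth via the copula identity r = 2 sin(pi rho / 6).
    """
    cfg.validate()
    rng = _rng(cfg, "latent")
    z0 = rng.standard_normal(cfg.n_genes)
    out: dict[str, np.ndarray] = {"breadth": norm.cdf(z0)}
    for name in sorted(cfg.breadth_feature_rho):
        rho_s = cfg.breadth_feature_rho[name]
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        eps = rng.standard_normal(cfg.n_genes)
        out[name] = r * z0 + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    return out


def generate_gene_models(cfg: SyntheticConfig) -> pd.DataFrame:
    """Single-exon gene models tiled over a toy genome.

    Genes are non-overlapping fixed-length intervals on a few contigs
    with alternating strands — enough to exercise interval-overlap
    mapping without realistic annotation.
    """
    cfg.validate()
    ids = gene_ids(cfg)
    per_contig = int(np.ceil(cfg.n_genes / cfg.n_contigs))
    rows = []
    for i, gid in enumerate(ids):
        contig = f"chr{i // per_contig + 1}"
        k = i % per_contig
        start = k * (cfg.gene_length + cfg.gene_gap)
        rows.append(
            (gid, f"{gid}.t1", contig, start, start + cfg.gene_length, "+" if i % 2 == 0 else "-")
        )
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "contig", "start", "end", "strand"])


def generate_peak_profiles(
    cfg: SyntheticConfig,
) -> tuple[list[ConditionProfile], GroundTruth]:
    """Per-condition, per-replicate m6A peak profiles.

    Peak presence per (gene, condition) is Bernoulli with probability
    ``floor + (ceil - floor) * breadth`` — monotone in the latent
    breadth. Present gene-conditions get a log-normal base enrichment
    total; each replicate multiplies it by log-normal noise and splits
    it across 1–3 peaks placed inside the gene interval. A configured
    fraction of conditions carries a perturbed core writer/eraser
    component in its metadata (all replicates of that condition).
    """
    cfg.validate()
    rng = _rng(cfg, "peaks")
    lat = _latents(cfg)
    genes = generate_gene_models(cfg)
    ids = gene_ids(cfg)
    conds = condition_ids(cfg)
    covered = covered_celltypes(cfg)

    p = cfg.peak_prob_floor + (cfg.peak_prob_ceil - cfg.peak_prob_floor) * lat["breadth"]
    present = rng.random((cfg.n_genes, cfg.n_conditions)) < p[:, None]
    base_score = np.exp(rng.normal(1.0, cfg.enrichment_sigma, size=present.shape))

    n_perturbed = int(round(cfg.frac_perturbed_profiles * cfg.n_conditions))
    perturbed_conds = rng.choice(cfg.n_conditions, size=n_perturbed, replace=False)
    core = sorted(CORE_COMPONENTS)
    perturbed_map = {
        conds[c]: frozenset({core[int(rng.integers(len(core)))]}) for c in sorted(perturbed_conds)
    }

    gene_start = genes["start"].to_numpy()
    gene_end = genes["end"].to_numpy()
    gene_contig = genes["contig"].to_numpy()
    gene_strand = genes["strand"].to_numpy()

    profiles = []
    for ci, cond in enumerate(conds):
        cell_type = covered[ci % len(covered)]
        gi = np.flatnonzero(present[:, ci])
        for r in range(cfg.n_replicates):
            rep_id = f"rep{r + 1}"
            rep_total = base_score[gi, ci] * np.exp(
                rng.normal(0.0, cfg.replicate_noise_sigma, size=len(gi))
            )
            npk = 1 + rng.poisson(0.7, size=len(gi))
            rows_g = np.repeat(gi, npk)
            rows_total = np.repeat(rep_total / npk, npk)
            span = gene_end[rows_g] - gene_start[rows_g]
            length = np.minimum(150, span)
            offset = (rng.random(len(rows_g)) * (span - length + 1)).astype(int)
            starts = gene_start[rows_g] + offset
            peaks = pd.DataFrame(
                {
                    "contig": gene_contig[rows_g],
                    "start": starts,
                    "end": starts + length,
                    "strand": gene_strand[rows_g],
                    "score": rows_total,
                }
            ).sort_values(["contig", "start", "end"], kind="mergesort").reset_index(drop=True)
            profiles.append(
                ConditionProfile(
                    condition_id=cond,
                    cell_type=cell_type,
                    replicate_id=rep_id,
                    perturbed_components=perturbed_map.get(cond, frozenset()),
                    peaks=peaks,
                )
            )
    truth = GroundTruth(latent_breadth=pd.Series(lat["breadth"], index=ids, name="latent_breadth"))
    return profiles, truth


def generate_expression_atlas(cfg: SyntheticConfig) -> pd.DataFrame:
    """Gene-by-tissue TPM matrix with breadth-linked tissue specificity.

    Each gene gets a target specificity tau drawn from the copula (so
    Spearman(breadth, tau) follows the configured target, negative by
    default — broadly methylated genes have flatter profiles). The
    profile realizes that tau: one maximal tissue, every other tissue
    expressed with probability 1 - tau at a log-normally damped level.
    A small configured fraction of genes is silent (all-zero row).
    """
    cfg.validate()
    rng = _rng(cfg, "atlas")
    lat = _latents(cfg)
    ids = gene_ids(cfg)
    tissues = tissue_names(cfg)
    n, m = cfg.n_genes, cfg.n_tissues

    u_tau = norm.cdf(lat["tissue_tau"])
    tau_target = 0.05 + 0.9 * u_tau
    max_val = np.exp(rng.normal(2.0, 0.6, size=n))
    # exponential level damping: x_i = max * exp(-lam * e_i) with e ~ Exp(1)
    # realizes E[tau] = 1 - 1/(1 + lam), so lam = t/(1 - t) targets tau = t.
    # Covered cell types get a sixth of the damping rate: cultured cell
    # lines express most genes above baseline, so the correction
    # denominator is nearly constant (matching the observation that the
    # corrected count distribution resembles the raw one).
    lam = tau_target / (1.0 - tau_target)
    lam_mat = np.tile(lam[:, None], (1, m))
    lam_mat[:, : cfg.n_cell_types] /= 6.0
    e = rng.exponential(1.0, size=(n, m))
    x = max_val[:, None] * np.exp(-lam_mat * e)
    peak_tissue = rng.integers(m, size=n)
    x[np.arange(n), peak_tissue] = max_val

    n_silent = int(round(cfg.frac_silent_genes * n))
    if n_silent:
        silent = rng.choice(n, size=n_silent, replace=False)
        x[silent, :] = 0.0
    atlas = pd.DataFrame(np.round(x, 4), index=pd.Index(ids, name="gene_id"), columns=tissues)
    return atlas


def generate_signaling_network(
    cfg: SyntheticConfig,
) -> tuple[SignalingNetwork, GroundTruth]:
    """Typed signed network with planted motif instances.

    Random activating/repressing/ppi edges over a subset of gene ids,
    plus the configured number of coherent/incoherent feedforward loops
    and positive/negative 2-cycles built from template sign patterns.
    Receptor and TF node sets are disjoint random subsets. Raises when a
    planted class is infeasible (too few nodes, or a repressing edge is
    required but n_repress is 0).
    """
    cfg.validate()
    rng = _rng(cfg, "network")
    lat = _latents(cfg)
    ids = np.array(gene_ids(cfg))
    n_nodes = min(cfg.n_nodes, cfg.n_genes)
    if n_nodes < 3:
        raise ValueError("n_nodes: signaling network needs >= 3 nodes")
    # higher-breadth genes are preferentially on the network (mirrors the
    # mapping of study genes onto curated pathways)
    order = np.argsort(-lat["breadth"] - 0.5 * rng.random(cfg.n_genes))
    nodes = np.sort(ids[order[:n_nodes]])

    for cls, count in cfg.n_planted_motifs.items():
        k, signs = _MOTIF_TEMPLATES[cls]
        if count > 0 and n_nodes < k:
            raise ValueError(f"n_planted_motifs[{cls}]: needs >= {k} nodes")
        if count > 0 and "-" in signs and cfg.n_repress == 0:
            raise ValueError(
                f"n_planted_motifs[{cls}]: requires repressing edges but n_repress is 0"
            )

    rows: list[tuple] = []

    def random_edges(n_edges: int, edge_type: str) -> None:
        if n_edges <= 0:
            return
        u = nodes[rng.integers(n_nodes, size=2 * n_edges)]
        v = nodes[rng.integers(n_nodes, size=2 * n_edges)]
        ok = u != v
        pairs = list(zip(u[ok], v[ok]))[:n_edges]
        rows.extend((a, b, edge_type) for a, b in pairs)

    random_edges(cfg.n_activate, "activate")
    random_edges(cfg.n_repress, "repress")
    random_edges(cfg.n_ppi, "ppi")

    planted: list[MotifInstance] = []
    for cls in sorted(cfg.n_planted_motifs):
        count = cfg.n_planted_motifs[cls]
        k, signs = _MOTIF_TEMPLATES[cls]
        for _ in range(count):
            tri = nodes[rng.choice(n_nodes, size=k, replace=False)]
            if k == 3:
                edge_pairs = [(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])]
            else:
                edge_pairs = [(tri[0], tri[1]), (tri[1], tri[0])]
            for (a, b), s in zip(edge_pairs, signs):
                rows.append((a, b, "activate" if s == "+" else "repress"))
            planted.append(MotifInstance(cls, tuple(tri), signs))

    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type"])
    remaining = [n for n in nodes]
    rng.shuffle(remaining)
    receptors = frozenset(remaining[: cfg.n_receptors])
    tfs = frozenset(remaining[cfg.n_receptors: cfg.n_receptors + cfg.n_tfs])
    net = SignalingNetwork(
        edges=edges, receptor_set=receptors, tf_set=tfs, extra_nodes=frozenset(nodes)
    )
    truth = GroundTruth(
        latent_breadth=pd.Series(lat["breadth"], index=list(ids), name="latent_breadth"),
        planted_motifs=planted,
    )
    return net, truth


def generate_ppi_network(cfg: SyntheticConfig) -> pd.DataFrame:
    """Binary PPI edge list with breadth-linked expected degrees.

    Target degrees are log-normal quantiles of the copula scores; the
    graph is sampled with the Chung–Lu expected-degree model, so the
    realized physical degree tracks the target up to sampling noise. A
    small admixture of 'genetic' interaction rows exercises the
    interaction-type filter downstream.
    """
    cfg.validate()
    rng = _rng(cfg, "ppi")
    lat = _latents(cfg)
    ids = gene_ids(cfg)
    w = np.exp(2.5 + 0.9 * lat["ppi_degree"])
    g = nx.expected_degree_graph(w, seed=int(rng.integers(2**31)), selfloops=False)
    rows = [(ids[u], ids[v], "physical") for u, v in g.edges()]
    n_genetic = max(1, len(rows) // 20)
    gu = rng.integers(cfg.n_genes, size=n_genetic)
    gv = rng.integers(cfg.n_genes, size=n_genetic)
    rows += [(ids[a], ids[b], "genetic") for a, b in zip(gu, gv) if a != b]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "interaction_type"])
    return df.sort_values(["gene_a", "gene_b", "interaction_type"], kind="mergesort").reset_index(drop=True)


def generate_evo_features(cfg: SyntheticConfig) -> pd.DataFrame:
    """Per-gene dN/dS ratios and ortholog counts.

    dN/dS is log-normal around 0.14 (monotone in its copula score, so
    the configured negative Spearman with breadth holds exactly);
    ortholog counts are log-normal around ~100 species.
    """
    cfg.validate()
    lat = _latents(cfg)
    dnds = np.exp(-2.0 + 0.6 * lat["dnds"])
    n_orth = np.round(np.exp(4.6 + 0.4 * lat["n_orthologs"])).astype(int)
    return pd.DataFrame(
        {"dnds": np.round(dnds, 5), "n_orthologs": n_orth},
        index=pd.Index(gene_ids(cfg), name="gene_id"),
    )


def generate_mirna_targets(cfg: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """miRNA–target interaction table with evidence counts and percentiles.

    The number of evidence-supported targeting miRNAs per gene is
    Poisson with a breadth-coupled rate. Pairs destined to survive the
    evidence filter get >= 1 strong or >= 3 weak records; an extra 30%
    of noise pairs carry insufficient evidence (never zero of both).
    Correlation coefficients are uniform on [-1, 1] and the two
    co-expression percentiles uniform on [0, 1]; the implied true
    co-expression class of every pair is recorded in the ground truth.
    """
    cfg.validate()
    rng = _rng(cfg, "mirna")
    lat = _latents(cfg)
    ids = gene_ids(cfg)
    mirnas = [f"miR-{i:04d}" for i in range(1, cfg.n_mirnas + 1)]

    z = lat["n_mirnas_total"]
    rate = cfg.mean_targets_per_gene * np.exp(0.7 * z - 0.245)
    k_keep = np.minimum(rng.poisson(rate), cfg.n_mirnas)
    rows = []
    for gi, k in enumerate(k_keep):
        if k == 0:
            continue
        chosen = rng.choice(cfg.n_mirnas, size=k, replace=False)
        for mi in chosen:
            if rng.random() < 0.6:
                strong, weak = 1 + rng.poisson(0.5), rng.poisson(1.0)
            else:
                strong, weak = 0, 3 + rng.poisson(1.0)
            rows.append((mirnas[mi], ids[gi], strong, weak))
    n_noise = int(0.3 * len(rows))
    for _ in range(n_noise):
        gi = int(rng.integers(cfg.n_genes))
        mi = int(rng.integers(cfg.n_mirnas))
        weak = int(rng.integers(1, 3))  # 1 or 2 weak, 0 strong: fails the filter
        rows.append((mirnas[mi], ids[gi], 0, weak))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_strong", "n_weak"])
    df = df.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
    df["correlation"] = np.round(rng.uniform(-1.0, 1.0, size=len(df)), 5)
    df["pct_mirna"] = np.round(rng.random(len(df)), 5)
    df["pct_gene"] = np.round(rng.random(len(df)), 5)
    df = df.sort_values(["gene_id", "mirna_id"], kind="mergesort").reset_index(drop=True)

    mr = np.sqrt(df["pct_mirna"] * df["pct_gene"])
    cls = np.full(len(df), "unclassified", dtype=object)
    cls[(df["correlation"] > 0) & (mr < 0.5)] = "positive"
    cls[(df["correlation"] < 0) & (mr > 0.5)] = "negative"
    truth = GroundTruth(
        latent_breadth=pd.Series(lat["breadth"], index=ids, name="latent_breadth"),
        coexpr_truth=df[["mirna_id", "gene_id"]].assign(true_class=cls),
    )
    return df, truth


@dataclass
class FixtureBundle:
    """Everything one synthetic run produces, plus its ground truth."""

    config: SyntheticConfig
    profiles: list[ConditionProfile]
    gene_models: pd.DataFrame
    atlas: pd.DataFrame
    covered_celltypes: list[str]
    network: SignalingNetwork
    ppi: pd.DataFrame
    evo: pd.DataFrame
    mirna: pd.DataFrame
    truth: GroundTruth


def generate_all(cfg: SyntheticConfig) -> FixtureBundle:
    """Run every generator under one config; shared latents keep the
    planted correlations consistent across outputs."""
    cfg.validate()
    profiles, truth_peaks = generate_peak_profiles(cfg)
    net, truth_net = generate_signaling_network(cfg)
    _, truth_mirna = generate_mirna_targets(cfg)
    truth = GroundTruth(
        latent_breadth=truth_peaks.latent_breadth,
        planted_motifs=truth_net.planted_motifs,
        coexpr_truth=truth_mirna.coexpr_truth,
    )
    return FixtureBundle(
        config=cfg,
        profiles=profiles,
        gene_models=generate_gene_models(cfg),
        atlas=generate_expression_atlas(cfg),
        covered_celltypes=covered_celltypes(cfg),
        network=net,
        ppi=generate_ppi_network(cfg),
        evo=generate_evo_features(cfg),
        mirna=generate_mirna_targets(cfg)[0],
        truth=truth,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(bundle: FixtureBundle, directory: str | Path) -> dict:
    """Write every fixture file plus a JSON manifest with config, seed
    and per-file SHA-256 hashes. Identical configs yield identical
    hashes."""
    root = Path(directory)
    peaks_dir = root / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)

    meta_rows = []
    for p in bundle.profiles:
        fname = f"{p.condition_id}_{p.replicate_id}.bed"
        bed = p.peaks.copy()
        bed.insert(3, "name", [f"peak{i}" for i in range(len(bed))])
        bed = bed[["contig", "start", "end", "name", "score", "strand"]]
        bed.to_csv(peaks_dir / fname, sep="\t", index=False, header=False,
                   float_format="%.6g", lineterminator="\n")
        meta_rows.append(
            (p.condition_id, p.cell_type, p.replicate_id, ",".join(sorted(p.perturbed_components)))
        )
    meta = pd.DataFrame(meta_rows, columns=["condition_id", "cell_type", "replicate_id", "perturbed_components"])
    _write_tsv(meta, root / "meta.tsv", index=False)

    # gene models as BED12 (single-exon transcripts)
    g = bundle.gene_models
    bed12 = pd.DataFrame(
        {
            "contig": g["contig"], "start": g["start"], "end": g["end"],
            "name": g["gene_id"] + "|" + g["transcript_id"],
            "score": 0, "strand": g["strand"],
            "thickStart": g["start"], "thickEnd": g["end"], "itemRgb": "0,0,0",
            "blockCount": 1, "blockSizes": (g["end"] - g["start"]).astype(str) + ",",
            "blockStarts": "0,",
        }
    )
    bed12.to_csv(root / "genes.bed", sep="\t", index=False, header=False, lineterminator="\n")

    _write_tsv(bundle.atlas, root / "expression.tsv", index=True)
    (root / "covered_celltypes.txt").write_text("\n".join(bundle.covered_celltypes) + "\n")
    _write_tsv(bundle.network.edges, root / "network.tsv", index=False)
    (root / "receptors.txt").write_text("\n".join(sorted(bundle.network.receptor_set)) + "\n")
    (root / "tfs.txt").write_text("\n".join(sorted(bundle.network.tf_set)) + "\n")
    (root / "network_nodes.txt").write_text("\n".join(sorted(bundle.network.nodes)) + "\n")
    _write_tsv(bundle.ppi, root / "ppi.tsv", index=False)
    _write_tsv(bundle.evo, root / "evo.tsv", index=True)
    _write_tsv(bundle.mirna, root / "mirna.tsv", index=False)

    truth_dir = root / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    _write_tsv(bundle.truth.latent_breadth.rename_axis("gene_id").to_frame(), truth_dir / "latent_breadth.tsv", index=True)
    planted = pd.DataFrame(
        [
            (m.motif_class, m.label, ";".join(m.nodes), "".join(m.edge_signs))
            for m in bundle.truth.planted_motifs
        ],
        columns=["motif_class", "label", "nodes", "edge_signs"],
    )
    _write_tsv(planted, truth_dir / "planted_motifs.tsv", index=False)
    if bundle.truth.coexpr_truth is not None:
        _write_tsv(bundle.truth.coexpr_truth, truth_dir / "coexpr_truth.tsv", index=False)

    files = sorted(str(p.relative_to(root)) for p in root.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "files": {f: _sha256(root / f) for f in files},
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d fixture files to %s", len(files), root)
    return manifest
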