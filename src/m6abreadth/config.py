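"""Configuration objects for the synthetic-data generator and the pipeline.

Both configs are plain dataclasses with eager validation: every invalid
field raises :class:`ConfigError` naming the offending field, so CLI users
get actionable messages instead of downstream stack traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["ConfigError", "SyntheticConfig", "RunConfig"]

#: m6A writer/eraser core components whose perturbation invalidates a profile.
CORE_COMPONENTS = frozenset({"METTL3", "METTL14", "WTAP", "ALKBH5", "FTO"})


class ConfigError(ValueError):
    """Raised when a configuration field is out of its admissible range."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study-condition generator.

    The defaults mirror the real study design this generator emulates:
    methylation profiles over 38 perturbation-free conditions, an
    expression atlas over 79 tissues of which a subset is covered by the
    methylation studies, and gene-importance features whose rank
    correlation with the latent regulation breadth is planted through a
    Gaussian copula (``breadth_feature_rho``).
    """

    n_genes: int = 5000
    n_conditions: int = 38
    n_replicates: int = 2
    n_cell_types: int = 8  # tissues flagged as covered by methylation studies
    n_tissues: int = 79
    seed: int = 0
    #: target Spearman correlation between latent breadth and each feature
    breadth_feature_rho: Mapping[str, float] = field(
        default_factory=lambda: {
            "ppi_degree": 0.3,
            "tissue_tau": -0.3,
            "dnds": -0.3,
            "n_mirnas_total": 0.2,
            "n_orthologs": 0.0,
        }
    )
    frac_perturbed_profiles: float = 0.1
    # signaling network block
    n_nodes: int = 300
    n_activate: int = 500
    n_repress: int = 250
    n_ppi: int = 400
    n_receptors: int = 30
    n_tfs: int = 40
    n_planted_motifs: Mapping[str, int] = field(
        default_factory=lambda: {"CFF": 5, "IFF": 5, "PFB": 5, "NFB": 5}
    )
    # miRNA block
    n_mirnas: int = 300
    mean_targets_per_gene: float = 2.0
    # toy genome
    n_contigs: int = 3
    gene_length: int = 1000
    gene_gap: int = 500
    # peak emission
    peak_prob_floor: float = 0.02
    peak_prob_ceil: float = 0.98
    enrichment_sigma: float = 0.5
    replicate_noise_sigma: float = 0.25
    frac_silent_genes: float = 0.01  # genes with an all-zero expression row

    def validate(self) -> "SyntheticConfig":
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(self.n_conditions >= 1, "n_conditions", "must be >= 1")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.n_tissues >= 2, "n_tissues", "must be >= 2")
        _require(
            1 <= self.n_cell_types <= self.n_tissues,
            "n_cell_types",
            "must be in [1, n_tissues]",
        )
        _require(
            0.0 <= self.frac_perturbed_profiles <= 1.0,
            "frac_perturbed_profiles",
            "must be in [0, 1]",
        )
        for name, rho in self.breadth_feature_rho.items():
            _require(
                -1.0 <= rho <= 1.0,
                f"breadth_feature_rho[{name}]",
                "must be in [-1, 1]",
            )
        _require(self.n_nodes >= 3, "n_nodes", "must be >= 3")
        for k in ("n_activate", "n_repress", "n_ppi"):
            _require(getattr(self, k) >= 0, k, "must be >= 0")
        for cls, n in self.n_planted_motifs.items():
            _require(cls in {"CFF", "IFF", "PFB", "NFB"}, "n_planted_motifs", f"unknown motif class {cls!r}")
            _require(n >= 0, f"n_planted_motifs[{cls}]", "must be >= 0")
        _require(self.n_receptors >= 1, "n_receptors", "must be >= 1")
        _require(self.n_tfs >= 1, "n_tfs", "must be >= 1")
        _require(self.n_mirnas >= 1, "n_mirnas", "must be >= 1")
        _require(
            0.0 < self.peak_prob_floor < self.peak_prob_ceil <= 1.0,
            "peak_prob_floor",
            "need 0 < floor < ceil <= 1",
        )
        _require(0.0 <= self.frac_silent_genes < 1.0, "frac_silent_genes", "must be in [0, 1)")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["breadth_feature_rho"] = dict(self.breadth_feature_rho)
        d["n_planted_motifs"] = dict(self.n_planted_motifs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown synthetic config field(s): {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Thresholds default to the comparative study's published rules: genes
    with corrected condition count > 3.5 are "frequently regulated",
    <= 1.5 "occasionally regulated"; baseline expression means TPM > 0.5;
    motif enrichment uses 10,000 resampling trials; the smoothing export
    trims the top 0.5% of the predictor.
    """

    outdir: str = "m6abreadth_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    # input paths (used when synthetic is None)
    peaks_dir: str | None = None
    meta_path: str | None = None
    atlas_path: str | None = None
    genes_path: str | None = None
    network_path: str | None = None
    receptors_path: str | None = None
    tfs_path: str | None = None
    ppi_path: str | None = None
    evo_path: str | None = None
    mirna_path: str | None = None
    # thresholds
    freq_cutoff: float = 3.5
    occa_cutoff: float = 1.5
    tpm_cutoff: float = 0.5
    n_resamples: int = 10000
    trim_fraction: float = 0.005
    effector_mode: str = "tf"
    unstranded: bool = False

    def validate(self) -> "RunConfig":
        _require(self.freq_cutoff > self.occa_cutoff > 0, "freq_cutoff", "need freq_cutoff > occa_cutoff > 0")
        _require(self.tpm_cutoff >= 0, "tpm_cutoff", "must be >= 0")
        _require(self.n_resamples >= 1, "n_resamples", "must be >= 1")
        _require(0.0 <= self.trim_fraction < 1.0, "trim_fraction", "must be in [0, 1)")
        _require(self.effector_mode in {"topology", "tf"}, "effector_mode", "must be 'topology' or 'tf'")
        if self.synthetic is not None:
            self.synthetic.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig.from_dict(syn)
        return cfg.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d
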