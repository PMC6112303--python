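# m6abreadth

Tools for asking why some human genes carry the N6-methyladenosine
(m⁶A) RNA modification in almost every experimental condition while
others are methylated only sporadically. Starting from per-condition
MeRIP-seq peak tables, the package scores each gene's *m⁶A regulation
breadth*, splits genes into frequently (m⁶A-freq) and occasionally
(m⁶A-occa) methylated classes, and contrasts those classes across
gene-importance features (dN/dS, PPI degree, tissue specificity, miRNA
targeting) and signed signaling-network topology (signed degrees,
centralities, receptor-to-effector relative level, and feedforward /
feedback motif enrichment by resampling). It is aimed at
epitranscriptomics and network-biology analysts who have gene-level
peak calls and want the comparative analysis end-to-end.

## The statistics at the core

**Condition counting and classes.** Profiles in which a core m⁶A
writer or eraser (*METTL3*, *METTL14*, *WTAP*, *ALKBH5*, *FTO*) was
perturbed are discarded; replicate peak sets are unioned; a gene counts
as regulated under a condition if any peak overlaps any of its
transcripts. The raw count is corrected by the number of
profile-covered cell types where the gene has baseline expression
(TPM > 0.5):

    corrected = n_conditions_regulated / n_expressed_covered_celltypes

Genes with corrected count > 3.5 are m⁶A-freq, ≤ 1.5 are m⁶A-occa, and
expressed-but-never-methylated genes are m⁶A-none.

**Quantitative breadth.** Per condition, peak enrichment scores are
summed along each transcript, the gene takes the maximum transcript
total, replicates are averaged, and totals are log₁₀(x+1)-transformed.
Over the resulting per-condition vector x the specificity index

    τ = Σᵢ (1 − xᵢ / x_max) / (N − 1)

is computed and the breadth is 1 − τ ∈ [0, 1] (1 = methylated equally
everywhere, 0 = methylated in a single condition). The same τ on a
gene-by-tissue TPM matrix gives the tissue-specificity feature.

**Relative level.** In the signed signaling network (directed
activate/repress edges plus undirected PPI edges, traversable both
ways), a node's position between upstream receptors and downstream
effectors is d_up / (d_up + d_down), both distances along
direction-respecting shortest paths.

**Motif enrichment.** All signed three-node feedforward loops
(coherent/incoherent by the sign rule sign(a→c) = sign(a→b)·sign(b→c))
and two/three-node feedback cycles (positive/negative by sign product)
are enumerated, given canonical codes such as `IFF3a1i2abbc`, and a
gene set's total occurrence per code is compared against equally sized
random gene sets; a code is significant when the observed occurrence
beats more than 9500 of 10 000 resampling trials.

Group contrasts use the two-sided Wilcoxon rank-sum test (means ±
standard errors reported); threshold-free association uses Spearman
correlation against the corrected count or the breadth, with a 0.5%
upper-tail trim before LOESS smoothing export.

Because the original data sources are large external databases, the
package ships a seeded synthetic generator that emulates every input
schema and plants known rank correlations (via a Gaussian copula)
between a latent breadth and each feature, so the whole pipeline is
validated by parameter recovery.

## Worked example

```python
from m6abreadth import SyntheticConfig, build_gene_summary
from m6abreadth import synthetic as syn
from m6abreadth.features import compute_ppi_degree, tau_table
from m6abreadth.stats import wilcoxon_compare, spearman_correlate

cfg = SyntheticConfig(n_genes=2000, seed=7)
bundle = syn.generate_all(cfg)
summary = build_gene_summary(
    bundle.profiles, bundle.gene_models, bundle.atlas, bundle.covered_celltypes
)
print(summary["class_label"].value_counts().to_dict())

tau = tau_table(bundle.atlas).reindex(summary.index)
deg = compute_ppi_degree(bundle.ppi).reindex(summary.index, fill_value=0)
freq = summary["class_label"] == "freq"
occa = summary["class_label"] == "occa"

cmp = wilcoxon_compare(deg[freq], deg[occa], "ppi_degree", "freq", "occa")
print(f"PPI degree: {cmp.mean_a:.1f} ± {cmp.se_a:.2f} vs {cmp.mean_b:.1f} ± {cmp.se_b:.2f}, P = {cmp.p_value:.2e}")
corr = spearman_correlate(summary["breadth"], tau, "tissue_tau", "breadth")
print(f"Spearman(breadth, tau) = {corr.rho:.3f}, P = {corr.p_value:.2e}, n = {corr.n_used}")
```

prints

```
{'intermediate': 915, 'occa': 716, 'freq': 320, 'none': 29, 'unexpressed': 20}
PPI degree: 27.8 ± 1.87 vs 13.6 ± 0.55, P = 1.05e-24
Spearman(breadth, tau) = -0.278, P = 5.59e-36, n = 1951
```

Of 2000 synthetic genes, 320 are frequently and 716 occasionally
methylated; the frequently methylated group has roughly twice the PPI
degree (27.8 vs 13.6 interaction partners — the planted
importance signal, recovered with high confidence), and quantitative
breadth is negatively rank-correlated with tissue specificity (−0.278,
close to the planted −0.3): broadly methylated genes are broadly
expressed.

The same analysis is available from the shell:

```bash
m6abreadth synth --out fixtures --seed 7
m6abreadth compile --peaks fixtures/peaks --meta fixtures/meta.tsv \
    --atlas fixtures/expression.tsv --genes fixtures/genes.bed \
    --covered fixtures/covered_celltypes.txt --out summary.tsv
m6abreadth run --config run.yaml   # or everything at once
```

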