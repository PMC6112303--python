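# Methods

## Scope and model

The package operationalizes a comparative question: do genes that carry
m⁶A methylation across many experimental conditions differ
systematically — in conservation, interaction-network position,
expression breadth, miRNA targeting and signaling-network topology —
from genes methylated only occasionally? It does not call peaks, infer
edges, or analyze single-nucleotide sites; its inputs are gene-level
peak tables, an expression atlas, typed edge lists and per-gene feature
tables, and its outputs are per-gene summaries plus a comparison
surface (rank tests, rank correlations, motif enrichment).

## Condition counting and gene classes

A profile is one (condition, replicate) peak set with metadata. The
perturbation filter removes every profile in which a core writer or
eraser (*METTL3*, *METTL14*, *WTAP*, *ALKBH5*, *FTO*) was
experimentally perturbed, because such profiles report an engineered
rather than physiological methylome; perturbation of reader proteins
does not disqualify a profile. Replicate peak sets are merged by
interval union, so the binary per-condition site set is insensitive to
replicate count and duplicated calls.

Coordinates are 0-based half-open (BED); an overlap is an intersection
of at least one base. A gene is regulated under a condition if at least
one merged peak overlaps at least one of its transcripts on the
matching strand; peaks with strand "." match both strands, and an
`unstranded` switch ignores strand entirely (peak callers differ in
whether they emit stranded intervals). However many peaks a gene has, a
condition contributes at most 1 to its count.

The raw count is divided by the number of profile-covered cell types in
which the gene shows baseline expression, defined strictly as
TPM > 0.5. Genes expressed in none of the covered cell types (or absent
from the atlas) are labeled `unexpressed` and excluded from
classification rather than given an infinite corrected count — the
correction is meaningless without expression evidence. Thresholds:
corrected > 3.5 → `freq`; 0 < corrected ≤ 1.5 → `occa`; between →
`intermediate`; zero peaks but baseline expression in ≥ 1 covered cell
type → `none`. All three cutoffs (3.5, 1.5, 0.5) are config fields so
threshold-sensitivity analyses are one config edit.

## Quantitative regulation breadth

Per condition and replicate, enrichment scores are summed along each
transcript; multi-transcript genes keep the maximum transcript total;
replicate totals are averaged arithmetically (the stated order:
transcript sum → gene max → replicate mean) and then transformed as
log₁₀(x + 1). The +1 offset is the zero-handling choice: conditions
without peaks enter as exactly 0 and stay 0 after transformation, so a
never-methylated condition and a vanishing enrichment agree in the
limit. The per-gene vector of one transformed total per retained
condition is summarized by the specificity index

τ = Σᵢ (1 − xᵢ/x_max) / (N − 1),

and breadth = 1 − τ. τ is scale-invariant, so breadth is invariant to
multiplying all of a gene's raw scores by a constant only up to the +1
offset; this is asserted for the chosen transform in the tests. Genes
with zero total in every condition have undefined breadth and are
excluded. The same τ over the tissue atlas (raw TPM, normalized by the
row max; negative inputs clipped to 0 with a warning) gives the
tissue-specificity feature; all-zero rows are undefined and flagged.

## Gene-importance features

PPI degree counts distinct partners over physical interaction edges
only (genetic and protein–RNA rows are filtered; duplicates and
self-loops collapse). miRNA–target records are kept when supported by
≥ 1 strong or ≥ 3 weak evidence records. The mutual rank of a pair is
the geometric mean of the miRNA-side and gene-side co-expression
percentiles and is always recomputed from the two percentiles so the
invariant is enforceable; pairs with positive correlation and mutual
rank < 0.5 are positively co-expressed, negative correlation and
mutual rank > 0.5 negatively; boundary values (correlation exactly 0,
mutual rank exactly 0.5) remain unclassified because the boundary
behavior is not defined by the classification rule. miRNA counts are
per distinct miRNA identifier; 3p/5p isoforms are not collapsed. The
feature table is an outer join on gene id with explicit missingness; a
duplicate gene id within one source is rejected as a data error.

## Signaling-network topology

The network mixes directed activating/repressing edges with undirected
PPI edges. Design choices, where the convention was genuinely open:

* Signed degrees (four directional counts) exclude PPI edges entirely,
  per the explicit activating/repressing split.
* Paths, betweenness and closeness run on the directed graph with PPI
  edges traversable in both directions: they are physical adapter
  links, and excluding them disconnects real networks. A
  `--paths-ignore-ppi`-style alternative can be had by loading the
  network without its ppi rows.
* Closeness uses outgoing distances and averages over the reachable
  set only; betweenness is normalized by (n−1)(n−2). Eigenvector
  centrality and transitivity (local clustering) use the undirected
  projection. Isolated nodes get 0 by convention.
* Distances are unweighted hop counts (no edge weights exist).

Feedback removal deletes every directed signed edge whose endpoints
share a strongly connected component (equivalently, every edge on a
directed cycle); the residual is acyclic by construction. Effectors are
either the zero-out-degree nodes of that residual (`topology` mode) or
the annotated transcription factors verbatim (`tf` mode, robust to
incomplete edge sets). The relative level of a node is
d_up/(d_up + d_down) with d_up the shortest directed distance from any
receptor and d_down the shortest directed distance to any effector;
it is undefined when either distance is infinite, and a node that is
both receptor and effector (0/0) takes 0.5 by symmetry.

## Motif catalog and enrichment

The catalog covers three-node feedforward loops and feedback cycles of
length 2 and 3 over signed edges only (PPI excluded); parallel edges of
opposite sign between one pair yield separate instances. A feedforward
loop is coherent iff the direct-edge sign equals the product of the
two path signs; a cycle is positive/negative by its sign product.
Canonical codes are CLASS + node count + `a`/`i` sign counts + the
positions of the majority-sign edges (`ab`, `bc`, `ac` for feedforward
loops; cycle positions after rotating to the lexicographically
smallest sign sequence, `+` before `−`; on a sign tie the activating
positions are listed). The published code grammar is illustrated by a
single example, so this grammar is a deterministic reconstruction: it
reproduces that example and maps isomorphic signed topologies to
identical codes, which is what the occurrence counting requires.

Enrichment of a gene set: observed = summed occurrences of the set's
genes for a code; each of n trials draws an equally sized set uniformly
without replacement from all network genes; the code is significant
when observed is strictly greater than the trial sum in more than 95%
of trials (ties do not count as greater, which makes the rule
conservative under heavily tied counts). The reported empirical P is
1 − n_greater/n floored at 1/(n+1) so it is never zero, while the
significance flag uses the literal >95% rule. The default is 10 000
trials.

## Comparison surface

Group contrasts are two-sided Wilcoxon rank-sum tests (normal
approximation with tie correction) reported as mean ± standard error
(sd/√n; the dispersion convention is a documented choice).
Associations are Spearman correlations with average-rank ties and
asymptotic p-values, pairwise-complete per feature. Raw p-values drive
nothing downstream; a Benjamini–Hochberg column is emitted for
convenience only. Before LOESS export the top 0.5% of the predictor is
trimmed (strictly above the 99.5th percentile), because extreme
corrected counts carry high feature variance and skew local
regression; smoothing uses span 0.75 and is export-only.

## Synthetic benchmark

The generator emulates the schemas of the real inputs (peak BED +
condition metadata, gene-by-tissue TPM matrix, typed signed edge list
with receptor/TF annotations, binary PPI list, evolutionary feature
table, miRNA–target table) and plants recoverable structure:

* One latent breadth per gene, uniform(0,1). Feature–breadth rank
  correlations are induced by a Gaussian copula with Pearson parameter
  r = 2 sin(πρ/6), making the Spearman target exact in expectation.
  Defaults: PPI degree +0.3, tissue τ −0.3, dN/dS −0.3, miRNA count
  +0.2, orthologs 0.
* Peak presence per (gene, condition) is Bernoulli with probability
  linear in breadth between 0.02 and 0.98 over 38 conditions × 2
  replicates; enrichment totals are log-normal with multiplicative
  replicate noise (σ = 0.25), split across 1–3 peaks inside the gene.
* The toy genome is 3 contigs of tiled single-exon genes (1 kb genes,
  0.5 kb gaps, alternating strands) — enough to exercise interval
  overlap and strand handling, with no claim to realistic annotation.
* The atlas realizes a target τ per gene by exponential level damping
  (rate λ = τ/(1−τ), giving E[τ] = λ/(1+λ)); the 8 covered cell types
  use λ/6, reflecting that cultured cell lines express most genes
  above baseline — this keeps the correction denominator nearly
  constant, consistent with the corrected-count distribution
  resembling the raw one. 1% of genes are silent (all-zero rows).
* The signed network has 300 nodes drawn preferentially from high-
  breadth genes, 500 activating / 250 repressing / 400 ppi random
  edges, and 5 planted instances each of coherent/incoherent
  feedforward loops and positive/negative 2-cycles, recorded in the
  ground truth.
* Degrees of the PPI graph follow log-normal copula targets through
  the Chung–Lu expected-degree model; ~5% of rows are `genetic`
  interactions that exercise the type filter. miRNA tables mix
  evidence-passing pairs (rate Poisson, breadth-coupled) with 30%
  insufficient-evidence noise pairs.

Every output is a pure function of the config including its seed
(independent deterministic substreams per stage), and fixture files are
written with fixed float formatting so reruns are byte-identical.

What the generator does **not** emulate: realistic marginal
distributions of condition counts (the real distribution is only known
coarsely), genomic annotation complexity (multi-exon transcripts,
overlapping genes), expression correlation structure across tissues,
scale-free network topology, or database-specific file quirks. Passing
recovery tests therefore demonstrates the pipeline's correctness and
statistical calibration, not claims about real m⁶A biology.

## Problem sizes and numerical notes

The test suite and the acceptance script use 5000 genes × 38 conditions
× 2 replicates for parameter recovery (recovery tolerance ±0.1 on
planted |ρ| = 0.3, which comfortably absorbs the attenuation from
Bernoulli/Poisson emission noise), 200 random ≤30-node networks for
exhaustive motif cross-checks, 100 random ≤25-node graphs for
shortest-path oracles, and 2000 outer repetitions × 1000 trials for the
resampling-calibration check; end-to-end determinism is verified on a
300-gene run. Group tests require ≥ 2 finite values per group and
correlations ≥ 3 complete pairs and non-constant inputs; anything
smaller is skipped with a log entry rather than an error.

## Known limitations

Transcript-level sums use the transcript span as given rather than an
exonic projection (the appropriate choice depends on how peaks were
called). The breadth statistic treats conditions as exchangeable; it
does not model condition similarity (two cell lines from the same
tissue count as two conditions). The motif catalog stops at three
nodes. The resampling test conditions on the network and occurrence
matrix; it does not account for uncertainty in the network itself.
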