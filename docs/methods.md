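# Methods

## Scope and data model

`nichegraph` operates on two in-memory containers: a spot×gene `AnnData`
with lattice coordinates and sample/condition labels, and a cell×gene
`AnnData` reference atlas with cell-type, compartment, sample, and
condition labels. On disk these travel as MatrixMarket triplets with a
Space Ranger-style `tissue_positions.csv` (headered and headerless
dialects both accepted), derived tables as TSV, graphs as GraphML, and
maps/manifests as JSON.

## Preprocessing

QC bounds are mode-specific and strict (a unit exactly at a bound
survives): nuclei are removed at <200 detected genes, >15 000 UMI, >5 000
genes, or >2% mitochondrial fraction; cells at <200 genes, >25 000 UMI,
>6 000 genes, or >35% mitochondrial; spots at <500 or >35 000 UMI or >20%
mitochondrial. Mitochondrial fraction is computed on raw counts before
any filtering, over genes whose name starts `MT-`.

Normalization is logTP10K with a highly-expressed-gene exclusion applied
**per unit**: genes taking more than 5% of a unit's total counts are
excluded from that unit's size factor, but every gene — including excluded
ones — is scaled by it; the value is `ln(1 + count × 10⁴ / size_factor)`.
This is written by hand rather than delegated to scanpy's
`normalize_total(exclude_highly_expressed=True)`, which excludes a gene
globally when it crosses the fraction in *any* cell — a different rule.
Units whose size factor is zero (all-zero, or all counts excluded) are
flagged and dropped with a warning. The same rule is applied to cells and
spots; a flag (`exclude_highly_expressed=False`) disables the exclusion
for sensitivity analysis.

Sample-level categorizations: a sample is `ILD-PP^high` when ≥50%
(inclusive) of its annotated spots are preserved parenchyma; a library is
epithelial-enriched at >80% epithelial cells, else stromal- or
immune-enriched at >60%, else whole — rules applied in that order (ties
cannot arise between them).

## Deconvolution

Reference profiles are per-type mean raw counts over at most 7 500 cells
per type (seeded downsampling). Each spot is decomposed by nonnegative
least squares of its library-size-scaled count vector against library-
size-scaled profiles, and the coefficients renormalized to sum to 1. This
is a deliberate simplification of Poisson platform-effect deconvolution
models: the downstream statistics consume only normalized weights, and an
adapter (`read_weights_tsv`) accepts externally computed weight tables so
any deconvolution tool's output can be dropped in. All-zero spots receive
a uniform row and are flagged.

Thresholding masks weights **strictly below** τ (default 0.01) to NaN; a
weight exactly at τ is kept. The source protocol states both "<0.01 set
to NaN" and "a threshold of >0.01"; the strict-less reading is implemented
and the conflict noted here. `calibrate_threshold` scans a τ grid and
reports the mean absolute difference between the number of assigned types
and an externally supplied cells-per-spot count (image segmentation is out
of scope; the synthetic ground truth provides the count in-package). The
calibration is only informative when the typical cells-per-spot is below
the number of reference types — with 12 types and ~20 cells/spot the
assigned-set size saturates at 12, so τ = 0 minimizes the error trivially.

## Colocalization networks

CoLS is the Spearman correlation (ties mid-ranked, p from the Student-t
approximation; exact permutation p available for n ≤ 10) between two cell
types' weight vectors across the spots of one condition. Masked weights
default to zero-fill — absence of a cell type is informative zero
abundance, not missingness — with a pairwise-complete option for
sensitivity analysis. Constant vectors yield undefined (NaN) correlations,
reported as missing; NaN p-values propagate through BH adjustment, whose
family is all unordered type pairs within one condition.

Edges require CoLS > 0 and adjusted p < α, with α = 0.05 for neighborhood
calls and α = 0.01 for the network graph. The graph is partitioned by
Clauset-Newman-Moore greedy modularity maximization on edge weights, with
nodes and edges fed in lexicographic order for deterministic tie-breaks.
Per-node modularity is defined as the node's row share of the modularity
sum, `q_i = Σ_j (A_ij/2m − k_i k_j/(2m)²) δ(c_i,c_j)`, so `Σ_i q_i = Q`
exactly. Conditions are compared by a two-sided Wilcoxon **rank-sum** test
on the two node-score distributions (unpaired, because the node sets can
differ between conditions); the exact distribution is used for tie-free
groups of ≤25 nodes, the normal approximation otherwise.

## Community enrichment

Per (category, cell type), a one-sided Welch t-test asks whether weights
are greater inside the category than in the background spots (pooled
variance available via flag; Welch is the default because weight variances
differ strongly across regions). When the category is a parenchymal
subgroup, spots of the other parenchymal subgroups are removed from the
background — exactly that removal, assertable by spot counts. Masked
weights count as zero. Both groups constant → p = 1. BH spans all
(category, type) pairs of one run; reported enrichments use α = 0.05, the
map that constrains the signaling network uses α = 0.01. Depletion is
deliberately untested.

## Signaling networks

Relevance gate per condition: one-vs-rest one-sided Wilcoxon rank-sum on
log-normalized expression, p < 0.05, and raw count > 0 in more than 10% of
the type's cells; types with <3 cells are excluded with a warning. An
interaction (ligand unit → receptor unit, complexes of up to 4 subunits)
is relevant for an ordered type pair when every ligand subunit is relevant
in the sender and every receptor subunit in the receiver. Constrained mode
counts a pair only when sender and receiver are enriched in at least one
common spatial community; edge weight is the interaction count.
Eigenvector centrality is computed on the symmetrized adjacency A + Aᵀ
(one score per node) by power iteration with a positive diagonal shift
(same eigenvectors; prevents oscillation on bipartite components),
normalized to a maximum of 1, per connected component for disconnected
graphs. A small curated L-R table ships with the package; user databases
load from CSV (`id, ligand_genes, receptor_genes`, subunits joined by
`+`).

## Driver prioritization

Expression arm: one-sided Wilcoxon of the target population against the
alveolar-lineage background on log-normalized values; keep TFs with
BH-adjusted p < 0.025 and logFC ≥ 0.5, where logFC is the difference of
log-space means (the log base and space are a declared convention, natural
log of the normalized values). Activity arm: regulon activity is the
weighted mean of gene-wise z-scored expression of the regulon's targets
(zero-variance genes score 0; regulons with <3 resolvable targets are
skipped) — a deterministic stand-in for regression-based regulon scoring,
to which it reduces under standardization; externally computed activity
tables can be supplied as a DataFrame. Keep TFs with mean activity
difference > 0.5 and adjusted p < 0.025. The myofibroblast variant uses
α = 0.01 and intersects the selections of two atlases plus a
spatial-community activity test (its spot universe defaults to all spots).
The two lists union with provenance (`expression`/`activity`/`both`).

Ligand ranking: per TF, the top-10 ligands by regulatory potential (ties
broken lexicographically — a declared convention); ligands recurring in ≥2
top-10 lists are kept; a candidate survives the receptor filter only if
every receptor gene is expressed in >5% of target cells in **every**
supplied atlas. Manual additions are explicit inputs flagged
`manual=True` — the judgment step is not automated.

Marker signatures: per gene and type, the one-vs-rest ROC AUC equals
U/(n₁n₂) from the Mann-Whitney statistic (ties count ½); genes with
AUC ≥ 0.65 form the atlas signature, ≥ 0.6 the bulk-mapping variant.
Module scores subtract, from the gene set's mean expression, the mean of
control genes drawn n_ctrl = 100 per set gene from the same
average-expression bin (n_bins = 24, seeded). A set shifted uniformly in
*all* units is invisible to this score by construction (controls are
matched on the observed mean); the score detects programs expressed in a
subset of units, which is what it is used for.

## Compositional differential abundance

Counts plus a 0.1 pseudocount are mapped to ALR coordinates
`y_k = ln((n_k + 0.1)/(n_ref + 0.1))` against a fixed, user-chosen
reference category. Each coordinate gets a Gaussian linear model with an
intercept, a condition indicator, and dummy-coded covariates
(modality/chemistry/study/fraction mirror the intended use); the condition
coefficient is tested by the exact F-form of the likelihood-ratio test
(the LR statistic is monotone in F, whose null distribution is exact under
the Gaussian model — preferable to the χ² asymptote at tens of samples).
BH across categories flags at FDR 0.20; the reference effect is 0 by
construction and never flagged; logFC is reported in log2. A singular
design raises an error naming the collinear terms; an all-zero reference
is an error, while all-zero non-reference categories are rescued by the
pseudocount.

This is a deterministic frequentist stand-in for Bayesian spike-and-slab
Dirichlet-multinomial models. One consequence: calls exactly at the FDR
boundary can flip when the reference is switched, because the reference's
own sampling noise is shared across all coordinates of one analysis.
Detection of genuinely shifted categories is reference-invariant in
practice (tested); the full flagged set is not guaranteed to be. A
dispersion-based `suggest_reference` utility ranks categories by
between-condition CLR stability without claiming equivalence to any
automatic-reference heuristic.

## Synthetic data: what it emulates, and what it does not

The generator plants every signal the pipeline is meant to detect:

- **Niches** are contiguous bands of lattice rows (hexagonal Space Ranger
  layout), each with a Dirichlet concentration over cell types; a spot's
  composition is a Dirichlet draw, its cell count Poisson (mean 20, the
  segmentation-derived figure), and its gene counts the sum of per-cell
  negative-binomial profile draws (drawn directly as NB with aggregated
  mean and dispersion — exact for shared per-gene dispersion).
- **Study conditions** (the defaults): 12 lung cell types in 4
  compartments, 160 genes, 500 spots/sample, 2 samples/condition. The
  control layout has six two-type niches mirroring intact anatomy
  (alveolus, vessel, airway-adjacent); the disease layout collapses them
  into two six-type mixed niches. This one swap produces the
  condition-specific colocalization differences and the modularity loss
  the comparison stages rest on. Truly colocalized pairs are those sharing
  a high-concentration niche (α > 1).
- **Counts** are negative-binomial with a single global dispersion
  (θ = 2), baseline per-gene means ~Gamma, and ≤8 boosted marker genes per
  type; a reserve of flat filler genes provides a null background for
  false-positive-rate checks. Mitochondrial genes are a named `MT-` subset
  so QC filters are exercisable.
- **Planted L-R pairs**: the ligand is induced (mean ≥ 2, hence expressed
  in ≫10% of cells by construction) in sender cells of the disease
  condition only; the receptor is constitutively expressed in the receiver
  type and near-silent (mean 0.02) elsewhere, so the >5% receptor filter
  is a real gate.
- **Planted regulons**: three TFs whose 8-gene target sets (and the TF
  itself) have means multiplied by the effect size (3.0) in the target
  population; the regulatory-potential prior links the two planted driver
  ligands to those TFs with high scores against a low-uniform background
  of 40 decoy ligands and 7 decoy TFs.
- **Abundance shifts** act on per-sample multinomial type proportions
  (natural-log fold changes; the reference type is pinned at 0);
  `simulate_composition_counts` exposes the same machinery without
  materializing gene counts.

All randomness descends from one seed through `SeedSequence` spawns, one
sub-stream per sample, so outputs are reproducible bit-for-bit.

Not emulated: platform effects between reference and spots (so
deconvolution recovery here is easier than on real data), batch effects,
doublets, ambient RNA, segmentation noise in cells-per-spot, spatial
autocorrelation within a niche beyond block membership, gene-gene
correlation beyond the planted structure, and realistic gene-count scale
(160 genes vs ~20 000). Passing tests therefore demonstrate that the
statistics recover what they are defined to recover under their stated
assumptions — not that any upstream integration step is robust to
real-data artifacts.

## Problem sizes and numerical choices

Recovery and calibration properties are measured at the scale the
generator defines: 1 000 spots/condition and 50 seeds for colocalization
recovery and modularity loss; ≥200 cells/type for the L-R zero-false-
negative property; 20 seeds for the driver cascade; 20 samples/condition
and 50 seeds for composition power and null calibration. Power iteration
for centrality runs to a 1e-12 step tolerance; Spearman p uses the t
approximation; BH is the standard step-up with monotonicity; greedy
partition ties are broken by lexicographic node order; ligand-rank ties by
ligand name. The pipeline manifest records the package version, seed,
every threshold, and SHA-256 digests of all outputs; identical
configuration and seed reproduce identical manifests byte-for-byte.

## Known limitations

- The NNLS stand-in ignores platform effects; use the external-weights
  adapter for production deconvolution.
- The DE gate is a plain one-vs-rest Wilcoxon; no covariate adjustment.
- The composition model treats ALR coordinates as Gaussian; with very few
  counts per category the pseudocount dominates.
- Eigenvector centrality on the symmetrized graph discards direction; left
  and right eigenvector options are exposed on request of the underlying
  function but the default reports one score per node.
- The CLI covers the pipeline and the main per-stage entry points, not
  every library option.
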