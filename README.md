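# nichegraph

Spatial niche analysis for spot-level transcriptomics of fibrotic lung
tissue (and, in general, any tissue profiled with a Visium-style array plus
a labeled single-cell/nucleus reference atlas).

In interstitial lung disease (ILD), progressive scarring does not just
change which cells are present — it dismantles the spatial organization of
the tissue. `nichegraph` quantifies that loss of organization and traces
its molecular drivers:

1. **Deconvolution weights.** Each array spot captures a mixture of cells.
   Spots are decomposed against cell-type mean reference profiles by
   nonnegative least squares, giving per-spot weights `w_{s,c}` normalized
   to `Σ_c w_{s,c} = 1`; weights below τ = 0.01 are masked (a spot cannot
   contain every cell type), a threshold calibrated against segmented
   cells-per-spot counts.
2. **Colocalization (CoLS) networks.** The colocalization score of two cell
   types is the Spearman correlation ρ of their weight vectors across the
   spots of one condition. Pairs with CoLS > 0 and Benjamini-Hochberg
   adjusted p < 0.01 become edges of an undirected weighted graph, which is
   partitioned by Clauset-Newman-Moore greedy modularity maximization:
   `Q = Σ_ij (A_ij/2m − k_i k_j/(2m)²) δ(c_i, c_j)`.
   Each node's summand share of Q is its per-node modularity, and disease
   vs control node-score distributions are compared with a two-sided
   Wilcoxon rank-sum test — loss of modularity is loss of tissue
   compartmentalization.
3. **Spatially constrained signaling networks.** A gene is *relevant* for a
   cell type if it is upregulated one-vs-rest (Wilcoxon, p < 0.05) and
   expressed in >10% of that type's cells. A ligand-receptor interaction
   counts for a sender→receiver pair when all ligand subunits are relevant
   in the sender and all receptor subunits in the receiver — and, in
   constrained mode, only when both types are enriched (one-sided t-test,
   adjusted p < 0.01) in at least one common spatial community. Interaction
   counts form a directed weighted graph ranked by eigenvector centrality.
4. **Driver-ligand prioritization.** Transcription factors enriched in a
   target population by expression (adjusted p < 0.025, logFC ≥ 0.5) or by
   regulon activity (mean difference > 0.5, adjusted p < 0.025) are matched
   against a ligand×TF regulatory-potential prior: each TF's top-10
   ligands are pooled, ligands recurring ≥ 2 times are kept, and candidates
   survive only if every receptor gene is expressed in >5% of target cells
   in every supplied atlas.
5. **Compositional differential abundance.** Sample×category counts are
   mapped, after a 0.1 pseudocount, to additive-log-ratio coordinates
   relative to a fixed reference category; a per-category linear model with
   condition and covariate terms is tested by a likelihood-ratio test and
   flagged at FDR < 20% (BH). The reference category's effect is 0 by
   construction.

A synthetic-data generator plants ground truth for every stage — niche-
structured Dirichlet spot mixtures on a hexagonal lattice, condition-
specific colocalization, ligand-receptor co-expression, TF regulons, and
abundance shifts — so the whole chain is testable without any external
download.

## Worked example

```python
from nichegraph import synthetic as syn, deconvolution as deconv, colocalization as coloc

cfg = syn.default_config(seed=0)            # 12 cell types, 2 conditions
profiles = syn.base_profiles(cfg)
spots, truth = syn.generate_spot_dataset(cfg, profiles)

wm = deconv.decompose(spots, profiles)      # NNLS weights, rows sum to 1
masked = wm.masked()                        # weights < 0.01 -> NaN

nets = {}
for cond in cfg.conditions:
    m = (spots.obs["condition"] == cond).to_numpy()
    cols, p = coloc.compute_cols(masked, condition_mask=m)
    net = coloc.build_network(cols, coloc.adjust_bh_pairs(p), mode="graph")
    nets[cond] = coloc.partition_greedy(net)
    print(f"{cond}: {net.graph.number_of_edges()} edges, "
          f"{len(set(net.partition.values()))} communities, Q = {net.Q:.3f}")

stat, pval = coloc.compare_modularity(nets["control"], nets["ILD"])
print(f"Wilcoxon rank-sum on node modularity: U = {stat:.1f}, p = {pval:.2e}")
```

prints

```
control: 6 edges, 6 communities, Q = 0.833
ILD: 30 edges, 2 communities, Q = 0.500
Wilcoxon rank-sum on node modularity: U = 144.0, p = 3.57e-05
```

The control tissue resolves into six two-type anatomical niches (high
modularity); the disease condition merges them into two mixed communities —
more edges, fewer communities, significantly lower per-node modularity.
That is the loss-of-compartmentalization signature the package measures.

The same analyses are available from the shell:

```sh
nichegraph run --seed 0 --outdir out/        # full pipeline + manifest
nichegraph simulate --seed 0 --outdir data/  # just the synthetic dataset
nichegraph compose --counts counts.tsv --conditions cond.tsv \
    --reference Arterial --fdr 0.2 --out abundance.tsv
```

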