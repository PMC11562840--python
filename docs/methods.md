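# Methods

## Model

`spagic` identifies spatial domains in spatial transcriptomics by learning a
per-spot embedding with a graph-convolutional auto-encoder trained under
three self-supervised constraints, then clustering the embedding.

**Spatial graph.** Spots with coordinates p_i are connected by a KNN graph:
spot similarity is the Gaussian kernel S_ij = exp(−‖p_i − p_j‖² / (2l²)),
and each spot links to its k most similar spots. Because the kernel is
strictly decreasing in distance, the selected neighbors — and hence the
graph — do not depend on the bandwidth l; l is kept so the similarity
matrix itself is computable and reportable. The directed KNN relation is
symmetrized by OR, self-loops are added (Ã = A + I) and the propagation
operator is the symmetric normalization D^{−1/2} Ã D^{−1/2}.

**Auto-encoder.** The encoder applies two graph-convolution layers
(σ(Â X W), widths 512 then 64) and the decoder mirrors them back to the
gene dimension. The final layer of each half is linear by default: the
embedding must reach negative values for cosine similarity and
Gaussian-mixture clustering to behave sensibly, and the reconstruction must
reach the negative values present in the standardized input. Both choices
are configurable (`final_linear`). Weights are Glorot-uniform initialized
under the run seed. There is no dropout or batch norm.

**Objectives.** With Z the embedding and H the reconstruction:

- reconstruction: L_mse = (1/N) Σ_i ‖X_i − H_i‖² (per-spot squared error
  summed over genes, averaged over spots);
- edge-wise constraint: binary cross-entropy between Ã and sigmoid(Z Zᵀ)
  over all N² ordered pairs;
- neighborhood-wise constraint: mean per-spot KL divergence between the
  row-softmax of Z Zᵀ and a prior obtained by row-normalizing Ã after
  flooring zeros at ε = 1e−12 (the floor keeps the divergence finite where
  Ã_ij = 0 while leaving neighbor mass essentially untouched);
- contrast: an InfoNCE-like term with cosine similarity and temperature τ.
  Per anchor, the positive set is its spatial neighbors and the negative
  set its non-neighbors; the anchor itself is excluded from the denominator
  (including it would add a constant e^{1/τ} unrelated to structure). The
  default form is a neighbor-sum over non-neighbor-sum ratio rather than
  canonical InfoNCE; the canonical denominator is available behind
  `canonical_infonce`.

The total is L = λ1 L_mse + λ2 (L_bce + L_kl) + λ3 L_con with defaults
(60, 0.01, 0.01), τ = 1. Ablation switches (`no_bce`, `no_kl`, `no_con`,
`no_G`, `only_mse`) drop terms from the total while still reporting them in
the per-epoch trace.

**Training.** Full-batch Adam (lr 0.001, weight decay 0.0001 added to the
raw gradient), default 600 epochs. All gradients are analytic (the losses'
gradients with respect to Z/H chain through the two GCN halves; the
propagation operator's symmetry is used in the backward pass) and are
verified against central finite differences in the test suite at relative
error below 1e−4. Runs are deterministic given the seed. Dense N×N loss
matrices are used up to 10 000 spots; beyond that the edge and neighborhood
terms switch to all positive pairs plus a seeded per-spot sample of
negatives.

**Clustering.** The default mirrors the mclust usage common in this
literature: a Gaussian mixture with shared ("EEE"-style, tied) covariance
fitted by EM on the embedding, initialized from ward hierarchical
clustering of a 20-component PCA projection, fixed seed. k-means, Louvain
(igraph multilevel) and Leiden on an embedding KNN graph are alternatives;
an Rscript bridge to the R mclust package provides exact reference parity
where R is available. Optional refinement replaces each label by the mode
among the spot's 50 spatially nearest neighbors (ties keep the spot's own
label, else the lowest label index), in a single pass; it is applied only
on request, because on small or thin-layered tissues a 50-neighbor window
spans domain boundaries and erodes them (see Limitations).

**Multiple slices.** Per-slice KNN graphs are placed on a block-diagonal
adjacency (no cross-slice edges; the locality tests verify no two-hop
leakage), expression is stacked over the intersection of per-slice filtered
gene sets, normalized per slice by default, HVG-selected and scaled
jointly, and trained exactly as a single slice. The joint embedding is then
batch-corrected. The default corrector aligns per-batch centroids
(optionally within coarse k-means clusters so slice composition differences
are respected); harmonypy is called instead when installed and requested.
Cross-slice spots act as contrastive negatives, consistent with the loss
definition (non-neighbors of an anchor include every spot in other slices).

## Preprocessing

Genes expressed in fewer than 3 spots are removed; counts are normalized to
a common library size (default 1e4, configurable — the normalization target
is not fixed by the method), log1p-transformed; if more than `n_hvg`
(default 3000) genes survive, the top highly variable genes
(dispersion-based selection on the log-normalized data) are kept; each gene
is then standardized, with (numerically) constant genes mapped to exactly
zero columns and no clipping by default. Coordinates are used as given;
only pairwise distances matter.

## Synthetic study conditions

The generator emulates laminar tissue: spots on a rows×cols lattice
partitioned into spatially contiguous domains (horizontal layers by
default; Voronoi blobs and square-annulus rings as alternatives — rings use
the Chebyshev radius so every band stays connected on the lattice). Each
domain owns `markers_per_domain` disjoint marker genes whose
negative-binomial mean is raised by `effect_size` on the log scale; counts
are gamma-Poisson draws (dispersion 0.3) thinned by element-wise dropout.
The reference conditions are a 20×20 lattice, 5 layers, 120 genes, 10
markers per domain, effect size 1.5, dropout 0.3, base mean 2.0 — small
enough that a full 600-epoch run takes well under two minutes on one CPU.
Multi-slice simulation reuses one domain template and applies a slice-wide
per-gene log-normal shift of scale `batch_shift` (default study value 0.5)
before drawing counts: a shift uniform across genes would cancel exactly
under library-size normalization, so a gene-wise shift is the minimal batch
effect that survives preprocessing.

What the generator does not emulate: platform geometry (hex grids, bead
sizes), within-domain expression gradients, cell-type mixtures within a
spot, or spatially correlated dropout. Passing end-to-end tests therefore
demonstrates correct mechanics and recoverability under idealized laminar
signal, not performance on real tissue.

## Numerical choices

- Sigmoid outputs are clamped to [1e−7, 1−1e−7] before logs in the BCE.
- Softmax rows that underflow to exact zeros contribute zero to the KL
  (xlogy convention); gradients go through log-softmax.
- cos(·, 0) is defined as 0 and its gradient as 0, so degenerate all-zero
  embeddings cannot produce NaN.
- KNN ties at equal distance are broken by spot index; refinement ties keep
  the current label. Both rules make runs bit-reproducible across
  platforms.
- Graphs are stored sparse; all oracle tests compare against dense
  references on ≤ 200 spots.

## Design choices where the method left room

- k defaults to 6 (mean neighbor count on the reference lattice ≈ 7.8,
  inside the 5–15 window the graph construction targets).
- The epoch default (600) follows common practice for peer GCN-based
  spatial-transcriptomics models; the method itself does not fix it and no
  early stopping is used.
- n_domains defaults to the annotated domain count when ground truth is
  present, otherwise it must be supplied (or a Louvain/Leiden resolution
  used instead).
- Whether multi-slice normalization is per-slice or joint is configurable;
  per-slice is the default since slices may differ in depth.

## Known limitations

- With the per-spot-sum reconstruction loss and default weights, the term's
  gradient dominates the graph and contrastive terms by orders of magnitude
  at small gene counts; on the 120-gene reference fixture, prolonged
  training slowly trades between-domain contrast for reconstruction detail,
  so domain-recovery ARI peaks in the low-hundreds of epochs and declines
  afterwards. A two-hop-smoothed PCA of the same input separates the
  generated domains almost perfectly, so this is a property of the
  objective balance, not missing signal. On real panels with thousands of
  genes the balance shifts and this effect is expected to be milder.
- The 50-neighbor refinement window is larger than one layer's thickness on
  the 400-spot reference lattice and can erode thin domains; refinement is
  therefore opt-in.
- The centroid batch corrector removes location shifts between slices; it
  does not model batch-specific mixing or scale effects the way a full
  harmony-style iteration does.
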