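# Methods

## Model

`spatialfuse` treats a tissue section as a graph over cells. Nodes carry two
feature vectors: the cell's preprocessed expression profile and a feature
summary of the 3×S×S histology patch centered on the cell. Edges connect
cells whose Euclidean distance in the shared pixel frame is ≤ *r* (a closed
ball; self-loops are not stored — every attention neighborhood re-includes
the cell itself explicitly). The closed-ball rule means coincident cells are
neighbors even at *r* = 0.

Three autoencoders share the graph. Every encoder and decoder layer is a
neighbor-attention layer: queries, keys and values are linear maps of the
input, attention weights are the softmax of scaled dot products over
{i} ∪ N(i), the output is the attention-weighted sum of values plus a bias,
passed through an ELU (the final decoder layer of each branch is linear).
The bias rides through the softmax unchanged because attention weights sum
to one; it lets the decoders capture per-gene means quickly. Encoders go
input → hidden (64) → latent (32); decoders mirror latent → hidden → output
with independent weights. The hybrid encoder consumes the concatenation of
the image and gene latents, and its decoder output — clipped below at zero —
is the *enhanced* (denoised) expression used downstream.

The training objective is the λ-weighted sum of per-branch mean squared
reconstruction errors against the normalized log expression,

  L = λ₁·L_image + λ₂·L_gene + L_hybrid,  λ₁ = λ₂ = 0.1,

optimized full-batch with Adam (lr 10⁻³, weight decay 10⁻⁴), global
gradient-norm clipping at 5, for 1,000 epochs by default. One integer seed
drives weight initialization (Glorot-uniform), so a fixed seed reproduces
the loss history bit-for-bit on one platform.

Two naming/architecture points are deliberate choices where the design was
open. First, the λ-weighted branch losses are bound by symbol consistency:
λ₁ weights the image branch, λ₂ the gene branch (at the default 0.1/0.1 the
distinction is numerically irrelevant). Second, all three branches
reconstruct expression by default — the image branch thereby learns to
predict expression from morphology; a config switch (`recon_img_target`)
instead makes it reconstruct its own input features. The hybrid branch
attends over the spatial graph in its own layers rather than fusing
per-cell only.

## Preprocessing and features

Expression preprocessing is fixed-order: gene-name deduplication (k-th
duplicate gets suffix `-(k−1)`, advancing past collisions), per-cell scaling
to a common total (default 10,000), then log1p. The composition is monotone
within each cell, so within-cell expression ranks are preserved. No
highly-variable-gene filtering happens by default; a top-k-variance filter
is available behind `hvg_top_k`.

Image patches are cell-centered half-open windows; non-integer coordinates
round half-away-from-zero; out-of-image pixels are zero (black) so border
behavior is deterministic and visible in tests. The built-in extractor is a
deterministic, training-free descriptor — per-channel histograms on a
spatial grid, channel means/stds, and a gradient-magnitude histogram
(defaults n_bins 16, grid 3, dim 454). It captures the coarse color/texture
contrasts that distinguish tissue compartments; it is not a learned
representation, and embeddings from pretrained pathology backbones can be
substituted through the precomputed-feature reader. Feature columns are
z-scored across cells (constant columns zeroed) before entering the model.

## Clustering and evaluation

Spatial domains are clusters of the hybrid latent z_h. The default
clusterer is a Gaussian mixture with tied covariance — the mclust-EEE model
that the spatial-domain benchmarking literature uses — with k set to the
number of annotated classes; full/diagonal covariance and k-means variants
are available. Agreement with annotations uses the adjusted Rand index
computed from the contingency table with exact binomial coefficients; the
implementation is cross-checked in the tests against an O(n²) pair-counting
oracle and an independent library implementation.

Marker genes are ranked one-vs-rest per cluster with a two-sided Wilcoxon
rank-sum test, Benjamini–Hochberg adjusted within each cluster's family;
the DEG calls require adjusted p < 0.05 and |log2 fold change| ≥ 0.25 by
default, with fold changes computed on expm1 of log-layer means.
Raw-vs-enhanced contrasts for a single gene use a paired two-sided t-test
on the same cells; an exact shift (zero-variance differences, nonzero mean)
reports the smallest positive float rather than failing. 2-D projections
use seeded UMAP.

## Synthetic benchmark

The generator emulates an annotated section: K spatial domains (equal
vertical stripes by default; Gaussian blobs and Voronoi layouts available),
disjoint blocks of domain-marker genes whose means are 2^lfc-fold elevated
in their domain, negative-binomial counts, and independent Bernoulli
dropout recorded in a ground-truth mask. The matched histology raster gives
each domain a color offset and a sinusoidal grating of domain-specific
frequency, both scaled by `texture_contrast`, over seeded
domain-independent pixel noise, with identical dark nuclei ellipses at
every cell; at contrast 0 the image carries no domain information, giving a
clean modality-ablation control. Image noise and count noise are
conditionally independent given the domain labels, so downstream fusion
gains are attributable to the image carrying domain signal.

Default study conditions: 800 cells, 200 genes, 4 domains, 30 markers per
domain at log2 fold change 2, base mean 1 count/gene, dispersion 0.3,
dropout 0.6, 480 px image, contrast 0.8. The marker fraction (60% of the
panel) reflects curated spatial panels, which are designed so that most
genes discriminate tissue compartments; the base mean of ~1 count/gene
matches imaging-platform depth, where much of the biological signal lives
in the detection (zero/nonzero) pattern — as it does here. With 5% marker
genes, expression-only clustering collapses to near-chance ARI, which no
real annotated section shows.

What the generator does **not** emulate: spatial expression gradients
within a domain, cell-type mixtures within domains, segmentation errors,
gene-gene correlation beyond domain structure, realistic H&E stain
appearance, or spatially correlated dropout. Passing tests therefore show
that the architecture fuses a domain-informative image signal with sparse
counts and recovers planted structure — not that it handles every artifact
of real acquisitions.

## Desk-scale protocol and numerical choices

The benchmark experiments (`spatialfuse.benchmark.run_pipeline`) use 200
training epochs, graph radius 30 px (mean degree ≈ 6–9, in line with the
hexagonal-lattice neighborhoods and radius-tuned graphs used on real
sections) and 64 px patches (several texture periods, the analogue of the
240 px patches at real tissue scale). The expression-only reference
embedding is a 20-component PCA of the normalized layer, clustered with the
same mixture model and k.

Numerical details: softmax per neighborhood is computed with max
subtraction; segment reductions use sorted-source `reduceat` and a sparse
scatter matrix, keeping the full-graph pass O(E); ELU gradients are exact
at the kink's right limit; degenerate clusterings (both partitions trivial)
define ARI as 1 when identical and 0 otherwise; all-zero expression rows
stay zero under normalization.

Two measured properties of the default conditions are worth knowing.
First, with 60% independent dropout, the best rank-32 linear reconstruction
of the normalized-log matrix retains ≈53% of its mean square, so a
latent-32 autoencoder cannot halve its reconstruction loss on this data —
the 200-epoch trajectory flattens around 70% of its initial value with all
structure below that being entry-level noise. Second, even with an
uninformative image (contrast 0), the hybrid embedding keeps a small ARI
advantage (≈ +0.08) over non-spatial PCA, because its attention layers
smooth over spatial neighbors and the domains are spatially contiguous;
the image-attributable gain is the difference between the contrast-0.8 and
contrast-0 advantages (≈ +0.28 vs ≈ +0.08 on three seeds).

## Limitations

* Full-batch training holds the whole graph in memory; 10⁵-cell sections
  fit, but minibatching over neighborhoods is an extension point, not
  implemented.
* The built-in extractor sees color and texture, not cell morphology
  proper; real-data performance depends on plugging in a pathology
  foundation-model embedding.
* The number of domains k must be supplied (as in benchmark practice);
  there is no model-selection step.
* Bit-exact reproducibility holds per platform/BLAS, not across platforms.
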