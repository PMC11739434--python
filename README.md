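# spatialfuse

Multimodal fusion of histology images and single-cell spatial
transcriptomics. `spatialfuse` denoises sparse spatial expression data and
identifies spatial tissue domains by fusing two views of every cell — its
transcriptome and the morphology of the tissue around it — with a hybrid
graph-attention autoencoder, then feeds the denoised ("enhanced")
expression into sharper marker-gene and differential-expression analysis.

It is aimed at users of imaging-based single-cell spatial platforms
(NanoString CosMx-class panels) and spot-based platforms (10x Visium-class),
where per-cell counts are heavily zero-inflated and expression-only
clustering of the tissue into domains is noisy, while the co-registered
H&E/IF image carries strong, untapped domain signal.

## The model

Cells form a spatial graph: nodes are cells, and two cells are connected
when their Euclidean distance is at most a radius *r* (closed ball; presets
*r* = 80 px lung, 300 px breast, 20 px colorectal). Three autoencoders share
this graph, each built from neighbor-attention layers in which cell *i*
attends over {*i*} ∪ N(*i*):

    out_i = ELU( Σ_{j ∈ {i}∪N(i)} α_ij (x_j W_v) + b_v ),
    α_ij = softmax_j( (x_i W_q)·(x_j W_k) / √d )

* the **image autoencoder** encodes per-cell image features z<sub>M</sub>
  (from 3×S×S cell-centered patches via a pluggable extractor),
* the **transcriptome autoencoder** encodes the normalized log expression,
* the **hybrid autoencoder** encodes the concatenation of the two latent
  embeddings into the terminal representation z<sub>h</sub>.

All three decode back into gene space and are trained self-supervised with
the weighted reconstruction loss

    L = λ₁ L_M + λ₂ L_g + L_h,     λ₁ = λ₂ = 0.1,

each term a mean squared error against the normalized log expression.
Training follows Adam (lr 10⁻³, weight decay 10⁻⁴) with global
gradient-norm clipping at 5. Spatial domains are Gaussian-mixture clusters
of z<sub>h</sub>; agreement with annotations is scored with the adjusted
Rand index computed from the contingency table. The model is implemented in
NumPy with hand-derived gradients, checked against finite differences in
the test suite.

A fully specified synthetic-tissue generator (domains, marker genes,
negative-binomial counts, independent dropout, matched procedural histology
textures) provides ground truth for every stage, so the whole pipeline is
testable offline without downloads, GPUs or pretrained weights. External
pathology foundation-model embeddings can be plugged in through
`load_precomputed_features`.

## Worked example

```python
import spatialfuse as sf

# a seeded synthetic section: 800 cells, 200 genes, 4 striped domains,
# 60% dropout, histology textures correlated with domain identity
cfg = sf.SyntheticConfig(seed=1)
dataset, image, truth = sf.generate_benchmark(cfg)

sf.preprocess_dataset(dataset)                    # dedup -> normalize -> log1p
graph = sf.build_radius_graph(dataset.coords, radius=30)
patches = sf.crop_patches(image, dataset, size=64)
feats = sf.standardize_features(
    sf.extract_features(patches, sf.BuiltinTextureExtractor()))

model = sf.HybridGraphModel.from_dataset(dataset, feats, graph)
res = model.fit(epochs=200, seed=1)
print(res.summary())

labels = res.cluster(k=4, seed=1)
print("domain ARI:", round(sf.adjusted_rand_index(labels, truth.domain_labels), 3))
```

The summary reports the fit:

```
Hybrid Graph-Attention Autoencoder Results
==========================================================
No. cells:                  800
No. genes:                  200
Image feature dim:          454
Hidden / latent dim:        64 / 32
Attention heads:            1
Loss weights (λ1, λ2):      (0.1, 0.1)
Graph radius (px):          30
Mean degree / isolated:     9.06 / 0
Epochs (lr, wd):            200 (0.001, 0.0001)
Grad clip norm:             5.0
Seed:                       1
----------------------------------------------------------
Total loss (first→last):    8.136610 → 5.653590
  L_img:                    6.641935 → 4.753984
  L_gene:                   6.955910 → 4.746929
  L_hyb:                    6.776826 → 4.703499
Max post-clip grad norm:    1.9493
==========================================================
domain ARI: 0.85
```

The loss falls as all three branches learn to reconstruct expression; the
hybrid embedding recovers the planted domains with ARI 0.85, versus ≈0.54
for clustering a PCA of the expression alone — the difference is the image
modality plus spatial context. `res.enhance()` writes the denoised
expression (layer `"enhanced"`), which correlates markedly better with the
noiseless ground truth than the raw dropout-ridden counts do and from which
`rank_genes` re-finds the planted domain markers.

The same pipeline is scriptable stage by stage:

```bash
spatialfuse simulate --out run/ --seed 1
spatialfuse preprocess --archive run/dataset.h5ad
spatialfuse graph --archive run/dataset.h5ad --radius 30 --out run/edges.csv
spatialfuse features --archive run/dataset.h5ad --image run/image.png \
    --patch-size 64 --out run/features.csv
spatialfuse train --archive run/dataset.h5ad --features run/features.csv \
    --edges run/edges.csv --epochs 200 --seed 1 --out run/ckpt.npz
spatialfuse enhance --archive run/dataset.h5ad --features run/features.csv \
    --edges run/edges.csv --checkpoint run/ckpt.npz
spatialfuse cluster --archive run/dataset.h5ad --features run/features.csv \
    --edges run/edges.csv --checkpoint run/ckpt.npz --k 4 --seed 1 \
    --out run/labels.csv
spatialfuse evaluate --labels run/labels.csv --truth run/truth_labels.csv \
    --out run/ari.json
```

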