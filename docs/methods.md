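# Methods

## Problem setting

Tile-level tissue classifiers for colorectal-cancer histopathology need
training sets that are balanced across tissue classes and morphologically
diverse within each class. Manual region annotation under-samples rare
morphologies; sampling nearest cluster centroids after unsupervised
clustering over-samples the dense, homogeneous core of each cluster. This
package curates tiles by clustering autoencoder embeddings and then sampling
*across the distance distribution* of each cluster, so every stratum — from
prototypical center to atypical fringe — is represented before a human
reviews anything.

## Pipeline model

**Tissue mask.** The slide raster is block-averaged by a factor of 32 and
converted to HSV; the saturation channel is thresholded with Otsu's method
(tissue is stained and saturated, glass background is near-white and
unsaturated). The scalar threshold is recorded so tests can recompute the
mask pixel by pixel. A saturation channel with no spread yields an empty
mask rather than an arbitrary Otsu split. "Histogram-based thresholding" is
instantiated as Otsu because it is the standard parameter-free choice; the
statistic is isolated in one function and the recorded threshold makes any
replacement auditable.

**Tile extraction.** Non-overlapping 256×256 grid tiles are retained when
the mask covers ≥ 25% of their footprint — a deliberately low threshold that
keeps sparse tissues (adipose, mucin). The tissue fraction is computed on
the downsampled mask footprint (8×8 mask pixels per tile at the defaults),
not at full resolution: this matches the downsample-then-threshold order and
is ~1000× cheaper; the oracle tests recount the same mask exhaustively.
Partial edge tiles are dropped (the encoder requires exact 256² inputs).
QC then removes blank tiles (grayscale σ < 5 of 255) and artifact tiles
(> 20% saturated-black pixels, or variance-of-Laplacian < 10 indicating
extreme blur). These three QC constants are package defaults, configurable
per call — reasonable screens, not claims about any particular scanner.

**Autoencoder.** Encoder: six 3×3 convolutions with batch normalization and
LeakyReLU (slope 0.2), channels 32→64→128→256→512→512, the first five with
stride 2 — the unique six-layer schedule that takes 256→8 spatially while
ending at 512 channels, so the flattened latent is 8·8·512 = 32,768 and a
channel-wise GAP gives exactly 512. Decoder: the mirror with transposed
convolutions (stride-2 layers use output padding 1 to invert the downsample
exactly) and a final sigmoid, so reconstructions live in [0, 1].

The loss is `1 − mean SSIM(x, x̂)` with the canonical single-scale SSIM:
11×11 Gaussian window, σ = 1.5, C1 = (0.01 L)², C2 = (0.03 L)², L = 1,
evaluated per channel at fully supported window positions and averaged.
SSIM is chosen over MSE because it rewards reproducing local structure
(gland outlines, nuclear texture) rather than average color. The gradient
with respect to the reconstruction is analytic: the windowed statistics are
linear images of x̂, and the adjoint of a valid Gaussian correlation is a
full convolution with the same symmetric window. The implementation is
verified against finite differences and against scikit-image's SSIM to
1e−10.

Training uses Adam (lr 1e−4, β = 0.9/0.999) on shuffled mini-batches with
each tile augmented by a seeded random subset of: 90° rotations, horizontal/
vertical flips, small affine warps (±15°, ±8 px, scale 0.9–1.1), per-channel
color jitter (gain 0.8–1.2, offset ±0.1), and Gaussian blur (σ ≤ 1.5). The
optimizer and learning rate are sane defaults, configurable. The whole
network is NumPy: convolutions are einsums over strided sliding-window
views, transposed convolutions are zero-stuffed convolutions, and every
layer passes a finite-difference gradient check. A width-reduced
configuration (channels ÷ 8, identical shape contract, 4,096-d latent) is
the default for CPU-scale runs; the full-width architecture is used for the
dimensionality contract and is selected with `ae_width_factor: 1`.

**Embedding.** The frozen encoder's 8×8×512 map is flattened (C-order) to
the latent vector; GAP takes the mean over the 64 spatial positions of each
channel (512-d); PCA (centered SVD) reduces to 256. PCA is fitted per slide,
since each slide's tile population is clustered independently; k shrinks to
`min(256, n − 1, 512)` for small slides. Component signs are fixed by making
each component's largest-magnitude entry positive, so transforms are
reproducible across linear-algebra backends. Stage tags
(latent/pooled/reduced) travel with each matrix and clustering refuses
anything but reduced input.

**Clustering.** `K = max(1, round(n/m))` with m = 400 and
round-half-away-from-zero; m balances within-cluster variety against mixing
tissue types, and the rule is overridable. K-means is scikit-learn's seeded
k-means++ Lloyd implementation, best of n_init = 10 restarts, max_iter 300,
tol 1e−4; it never returns empty clusters. Centroid distances are computed
in the 256-d clustering space so distances and centroids are consistent.
Density-based alternatives (DBSCAN) are deliberately not offered: they lack
consistent cluster sizing, which the m-based rule depends on.

**Diversity sampling.** Per cluster: min–max normalize distances (all-equal
distances map to 0), stable-sort by (distance, tile_id), split into g = 5
contiguous equal-frequency bins — with n = qg + r, the first r bins (lowest
distances) get q + 1 tiles — and draw `max(1, round(0.2 · |bin|))` tiles
uniformly without replacement from each non-empty bin. The max(1, ·) floor
ensures tiny bins still contribute one tile. Ties at bin boundaries break by
tile_id; remainder placement at the low-distance end is arbitrary but fixed.
g and the fraction are first-class config (g = 2 reduces variation, g = 10
increases it). The audit manifest lists *every* cluster tile with its bin,
normalized distance and a selected flag.

**Curation.** Cluster labels follow a small state machine: seed → confirmed
or rejected; propagated proposals attach the seed's class to the nearest
unlabeled clusters (centroid-to-centroid distance, optional cap), never
overwrite seed/confirmed labels, and resolve contested neighbors by smaller
distance then smaller seed index. Export produces a GeoJSON
FeatureCollection of closed, counter-clockwise rectangle rings in level-0
pixel coordinates with `classification.name` properties (QuPath's dialect),
plus a plain CSV. Assembly requires every manifest row confirmed, rejects
duplicate tiles across classes, and caps each class (default 70,000) by a
seeded uniform subsample over lexicographically sorted tile ids, making it
idempotent.

**Orchestration.** Eight stages (synth, tile, train-ae, embed, cluster,
sample, export, assemble) share a work directory; each writes a JSON run
record (config hash, stage seed, inputs/outputs, counts) so the funnel
extracted → QC-passed → clustered → sampled → assembled is auditable.
Per-stage seeds derive from one master seed as
`(master · 1,000,003 + stage_index) mod 2³¹`. On synthetic slides the export
stage labels each cluster with the majority ground-truth texture of its
member tiles and marks it confirmed — a machine stand-in for the reviewer's
sign-off that keeps the pipeline runnable unattended; with real slides the
LabelBook is driven interactively and assembly refuses unconfirmed tiles.

## Synthetic slides

The generator renders seeded slides with polygon/rectangle regions carrying
one of four procedural texture families — thresholded Gaussian-field blobs,
sinusoidal stripes, salt-and-pepper speckle, flat color — over saturated,
stain-like base colors on a flat near-white background (245,245,245), plus a
pixel-exact integer label mask. It emulates what the pipeline needs: colored
tissue on pale glass, visually distinct region types, ground truth for
purity scoring. It does **not** emulate H&E stain physics, pyramidal
multi-resolution files, scanner artifacts, stain variation between slides,
or the soft boundaries and mixed-tissue tiles of real WSI. Passing tests
therefore demonstrate the machinery (masking, embedding, clustering,
sampling, bookkeeping) is correct and deterministic — not that the
autoencoder's embeddings separate real tissue types, which only a real-WSI
study can show.

## Problem sizes and numerical choices

Library-scale runs use deliberately small problems: training behavior is
demonstrated on 200 single-texture tiles for 5 epochs with the 1/8-width
encoder; purity and propagation on a 2560² four-texture slide (64 tissue
tiles); determinism on a 1536² slide with 2 training epochs; the exhaustive
K-means oracle on n = 8 points; the sliding-window SSIM oracle on 16×16
images. Degenerate inputs are pinned down explicitly: all-equal distances
normalize to 0; clusters smaller than g leave trailing bins empty; slides
with fewer than 257 tiles shrink PCA's k; a constant-saturation slide has an
empty tissue mask; K-means ties and neighbor ties break by index; empty tile
sets and unknown clusters raise.

## Limitations

- Embedding quality on real tissue is untested here by construction; the
  synthetic textures are far easier to separate than real morphologies.
- The per-slide PCA means embeddings are not comparable across slides;
  cross-slide label propagation is out of scope.
- The NumPy autoencoder is CPU-bound and single-threaded beyond BLAS; full
  width at the published training scale (100,000 tiles) is not practical
  without a GPU framework, though the architecture contract holds.
- QC thresholds are heuristic defaults; pen marks, coverslip edges and other
  scanner-specific artifacts have no dedicated detectors.
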