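# tilecurator

Building a tile-level training dataset from whole-slide histopathology
images (WSI) is slow and biased when done by hand: annotators gravitate to
visually familiar regions, rare morphologies are missed, and classes end up
imbalanced. `tilecurator` implements a semi-automated curation pipeline that
does the heavy lifting before a pathologist ever looks at a tile:

1. **Tile extraction** — non-overlapping 256×256 tiles are kept where a
   histogram-thresholded (Otsu on saturation, computed at a 32× downsample)
   tissue mask covers ≥ 25% of the tile; blank and artifact tiles are
   filtered out.
2. **Feature learning** — a six-layer convolutional autoencoder (batch norm
   + LeakyReLU, mirrored transposed-convolution decoder with sigmoid output)
   is trained on tiles with an SSIM reconstruction loss,
   `L = 1 − mean SSIM(x, x̂)`, under random rotations, flips, affine warps,
   color jitter and Gaussian blur. The frozen encoder maps a tile to an
   8×8×512 feature map — a 32,768-dimensional latent vector.
3. **Embedding** — channel-wise global average pooling compresses the latent
   to 512 dimensions; per-slide PCA reduces it to 256.
4. **Clustering** — K-means (seeded k-means++, Lloyd iterations) groups
   morphologically similar tiles, with `K = max(1, round(n / m))` so clusters
   average `m = 400` tiles. Each tile's diversity score is its Euclidean
   distance to its cluster centroid, `d_i = ‖v_i − c‖`.
5. **Diversity sampling** — per cluster, distances are min–max normalized to
   [0, 1], tiles are sorted and split into `g = 5` equal-frequency bins
   (sizes differ by at most one), and 20% of each bin is sampled uniformly.
   Sampling across bins — not just near the centroid — prevents
   over-representation of the dense cluster core and captures edge-of-cluster
   variants.
6. **Review and assembly** — a reviewer labels a seed cluster with one of
   nine tissue classes (ADI, LYM, MUS, FCT, MUC, NCS, BLD, TUM, NOR); the
   label is propagated as a proposal to the nearest unlabeled clusters in
   embedding space. Sampled tiles are exported as QuPath-compatible GeoJSON
   rectangles at their original slide coordinates for verification. Confirmed
   tiles are assembled into per-class folders with a per-class cap
   (70,000 at full scale) enforced by seeded subsampling.

Everything is testable without real WSI: a synthetic-slide module renders
seeded slides whose regions carry visually distinct parametric textures
(blobs, stripes, speckle, flat color) on a near-white background, with
pixel-level ground-truth label masks.

The autoencoder is implemented in pure NumPy (strided-view convolutions,
manual backprop, analytic SSIM gradient, Adam), so the package has no
deep-learning framework dependency and every layer is verified by
finite-difference gradient checks.

## Worked example

Run the whole pipeline on one synthetic slide:

```sh
tilecurator run-all --workdir work --seed 11
```

prints the audit funnel (counts in/out of every stage):

```
synth: width=1536
synth: height=1536
synth: regions=4
tile: grid_tiles=36
tile: tissue_tiles=16
tile: qc_flagged=0
tile: retained=16
train-ae: tiles=16
train-ae: epochs=3
embed: tiles=16
embed: latent_dim=4096
embed: pooled_dim=64
embed: reduced_dim=15
cluster: tiles=16
cluster: K=1
cluster: inertia_x1000=19034
sample: clusters=1
sample: tiles=16
sample: sampled=5
export: labeled_clusters=1
export: tiles=5
assemble: ADI=5
```

Reading the funnel: the 1536² slide has a 6×6 tile grid of which 16 tiles
meet the 25% tissue threshold (the four 512² texture regions) and none are
flagged by QC. The default config trains a width-reduced autoencoder
(1/8 channels, hence a 4,096-d latent pooling to 64; set
`ae_width_factor: 1` in the YAML config for the full 32,768 → 512
architecture). With 16 tiles, `K = round(16/400) = 1` cluster; five bins of
3–4 tiles each yield 5 sampled tiles (one per bin, the small-cluster
floor), which are auto-labeled from the synthetic ground truth, exported to
`work/export/annotations.geojson`, and assembled under `work/dataset/`.
Per-stage JSON run records land in `work/records/`.

Stages can equally be run one at a time (`tilecurator synth`, `tile`,
`train-ae`, `embed`, `cluster`, `sample`, `export`, `assemble`) against the
same work directory, with a YAML config overriding any default
(tile_size 256, downsample 32, tissue_threshold 0.25, m 400, g 5,
sample_fraction 0.2, per_class_cap 70000, ...).

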