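"""Encoder feature maps to clustering-ready vectors: GAP to 512, PCA to 256.

The pipeline is strictly staged: the flattened encoder latent (32,768-d
under the default architecture) is compressed by channel-wise global average
pooling (one value per channel, 512-d), then by PCA fitted per slide
(256 components, fewer when a slide has too few tiles for the rank). Stage
tags travel with the matrix so downstream clustering can refuse anything but
reduced vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autoencoder import Autoencoder, tiles_to_batch

STAGES = ("latent", "pooled", "reduced")


@dataclass
class EmbeddingMatrix:
    tile_ids: list[str]
    vectors: np.ndarray  # (n, d) float32
    stage: str
    slide_id: str = "slide"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.tile_ids):
            raise ValueError(
                f"vectors must be (n_tiles, d); got {self.vectors.shape} for {len(self.tile_ids)} tiles"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class PcaTransform:
    mean: np.ndarray  # (d,)
    components: np.ndarray  # (d, k), orthonormal columns
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    slide_id: str = "slide"

    @property
    def k(self) -> int:
        return self.components.shape[1]


def encode_tiles(model: Autoencoder, tiles: np.ndarray, tile_ids: list[str],
                 batch_size: int = 16, slide_id: str = "slide") -> EmbeddingMatrix:
    """Flattened latent vectors (row order = input order), inference mode.

    ``tiles`` is ``(n, H, W, 3)`` uint8 or float in [0, 1]; the latent is the
    C-order flattening of the encoder's (C, h, w) feature map.
    """
    if len(tile_ids) != tiles.shape[0]:
        raise ValueError("tile_ids must match the tile count")
    batch_all = tiles_to_batch(tiles)
    rows = []
    for start in range(0, batch_all.shape[0], batch_size):
        feats = model.encode(batch_all[start : start + batch_size])
        rows.append(feats.reshape(feats.shape[0], -1))
    vectors = np.concatenate(rows) if rows else np.empty((0, model.enc_config.latent_dim), dtype=np.float32)
    return EmbeddingMatrix(tile_ids=list(tile_ids), vectors=vectors, stage="latent", slide_id=slide_id)


def global_average_pool(latent: EmbeddingMatrix, feature_shape: tuple[int, int, int]) -> EmbeddingMatrix:
    """Channel-wise spatial mean: (C, h, w) latent rows -> C-dimensional rows."""
    if latent.stage != "latent":
        raise ValueError(f"global_average_pool expects stage 'latent', got {latent.stage!r}")
    c, h, w = feature_shape
    if latent.dim != c * h * w:
        raise ValueError(f"latent dim {latent.dim} does not match feature shape {feature_shape}")
    pooled = latent.vectors.reshape(latent.n, c, h * w).mean(axis=2)
    return EmbeddingMatrix(tile_ids=latent.tile_ids, vectors=pooled, stage="pooled", slide_id=latent.slide_id)


def fit_pca(pooled: EmbeddingMatrix, n_components: int = 256) -> PcaTransform:
    """Centered SVD PCA with a deterministic sign convention.

    ``k = min(n_components, n - 1, d)`` — a slide with fewer than
    ``n_components + 1`` tiles simply keeps every available component. Each
    component's largest-magnitude entry is made positive so the transform is
    reproducible across SVD implementations.
    """
    if pooled.n < 2:
        raise ValueError("PCA requires at least 2 tiles")
    x = pooled.vectors.astype(np.float64)
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, pooled.n - 1, pooled.dim)
    comps = vt[:k].T  # (d, k)
    signs = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    comps = comps * signs[None, :]
    var = s ** 2
    total = var.sum()
    ratios = var[:k] / total if total > 0 else np.zeros(k)
    return PcaTransform(mean=mean, components=comps, explained_variance_ratio=ratios,
                        slide_id=pooled.slide_id)


def apply_pca(transform: PcaTransform, pooled: EmbeddingMatrix) -> EmbeddingMatrix:
    if pooled.stage != "pooled":
        raise ValueError(f"apply_pca expects stage 'pooled', got {pooled.stage!r}")
    if pooled.dim != transform.mean.shape[0]:
        raise ValueError(f"dimension mismatch: transform is {transform.mean.shape[0]}-d, data is {pooled.dim}-d")
    reduced = (pooled.vectors.astype(np.float64) - transform.mean) @ transform.components
    return EmbeddingMatrix(tile_ids=pooled.tile_ids, vectors=reduced, stage="reduced",
                           slide_id=pooled.slide_id)


# -- persistence ------------------------------------------------------------------

def save_embedding(em: EmbeddingMatrix, path: str | Path) -> None:
    """Binary array + JSON sidecar; bit-exact round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), em.vectors)
    sidecar = {"slide_id": em.slide_id, "stage": em.stage, "tile_ids": em.tile_ids,
               "shape": list(em.vectors.shape), "dtype": str(em.vectors.dtype)}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_embedding(path: str | Path) -> EmbeddingMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    vectors = np.load(path.with_suffix(".npy"))
    return EmbeddingMatrix(tile_ids=sidecar["tile_ids"], vectors=vectors,
                           stage=sidecar["stage"], slide_id=sidecar["slide_id"])
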