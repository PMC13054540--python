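"""K-means over reduced embeddings, sized for ~400 tiles per cluster.

The cluster count is derived from a target mean cluster size ``m`` (default
400: large enough for morphologic variety inside a cluster, small enough
that a cluster stays one tissue type) as ``K = max(1, round(n / m))``.
Clustering is Lloyd's algorithm with seeded k-means++ initialization and
``n_init`` restarts (scikit-learn). Each tile's Euclidean distance to its
own centroid — the diversity axis used by the sampler — is computed in the
same reduced space the clustering ran in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .embedding import EmbeddingMatrix

DEFAULT_M = 400


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray  # (K, d)
    tile_ids: list[str]
    labels: np.ndarray  # (n,) cluster index per tile
    inertia: float
    distances: np.ndarray  # (n,) Euclidean distance to own centroid
    seed: int
    n_init: int
    max_iter: int
    tol: float
    slide_id: str = "slide"

    @property
    def assignments(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(self.tile_ids, self.labels)}

    def cluster_tile_ids(self, cluster_index: int) -> list[str]:
        if not 0 <= cluster_index < self.K:
            raise KeyError(f"cluster {cluster_index} out of range for K={self.K}")
        return [t for t, c in zip(self.tile_ids, self.labels) if c == cluster_index]


def choose_k(n_tiles: int, m: int = DEFAULT_M) -> int:
    """K = max(1, round(n/m)) with round-half-away-from-zero.

    With m=400: 4000 tiles -> K=10 (mean size 400); 1000 tiles -> K=3.
    """
    if n_tiles < 1 or m < 1:
        raise ValueError("n_tiles and m must be >= 1")
    return max(1, math.floor(n_tiles / m + 0.5))


def kmeans(reduced: EmbeddingMatrix, K: int, seed: int = 0, n_init: int = 10,
           max_iter: int = 300, tol: float = 1e-4) -> ClusterModel:
    """Seeded k-means++ Lloyd clustering, best of ``n_init`` restarts by inertia."""
    if reduced.stage != "reduced":
        raise ValueError(f"clustering requires stage 'reduced' embeddings, got {reduced.stage!r}")
    if reduced.n < K:
        raise ValueError(f"cannot form K={K} clusters from {reduced.n} tiles")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init, max_iter=max_iter,
                tol=tol, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(reduced.vectors.astype(np.float64))
    centroids = km.cluster_centers_
    distances = np.linalg.norm(reduced.vectors - centroids[labels], axis=1)
    return ClusterModel(K=K, centroids=centroids, tile_ids=list(reduced.tile_ids),
                        labels=labels.astype(np.int64), inertia=float(np.sum(distances ** 2)),
                        distances=distances, seed=seed, n_init=n_init, max_iter=max_iter,
                        tol=tol, slide_id=reduced.slide_id)


def centroid_distances(reduced: EmbeddingMatrix, model: ClusterModel) -> np.ndarray:
    """Per-tile Euclidean distance to the tile's own cluster centroid."""
    if list(reduced.tile_ids) != model.tile_ids:
        raise KeyError("embedding tile_ids do not match the fitted cluster model")
    return np.linalg.norm(reduced.vectors - model.centroids[model.labels], axis=1)


def neighbor_clusters(model: ClusterModel, cluster_index: int,
                      n_neighbors: int | None = None) -> list[tuple[int, float]]:
    """Other clusters ranked by ascending centroid-to-centroid distance.

    Ties break toward the smaller cluster index; at most ``K - 1`` entries.
    """
    if not 0 <= cluster_index < model.K:
        raise KeyError(f"cluster {cluster_index} out of range for K={model.K}")
    others = [i for i in range(model.K) if i != cluster_index]
    dists = np.linalg.norm(model.centroids[others] - model.centroids[cluster_index], axis=1)
    order = sorted(range(len(others)), key=lambda j: (dists[j], others[j]))
    ranked = [(others[j], float(dists[j])) for j in order]
    return ranked if n_neighbors is None else ranked[:n_neighbors]


# -- persistence ---------------------------------------------------------------

def save_cluster_model(model: ClusterModel, path: str | Path) -> None:
    """JSON params + .npy centroids + CSV of per-tile assignment and distance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"K": model.K, "inertia": model.inertia, "seed": model.seed, "n_init": model.n_init,
            "max_iter": model.max_iter, "tol": model.tol, "slide_id": model.slide_id}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.save(path.with_suffix(".npy"), model.centroids)
    pd.DataFrame({"tile_id": model.tile_ids, "cluster": model.labels,
                  "distance": model.distances}).to_csv(path.with_suffix(".csv"), index=False)


def load_cluster_model(path: str | Path) -> ClusterModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    centroids = np.load(path.with_suffix(".npy"))
    table = pd.read_csv(path.with_suffix(".csv"))
    return ClusterModel(K=meta["K"], centroids=centroids, tile_ids=table["tile_id"].tolist(),
                        labels=table["cluster"].to_numpy(dtype=np.int64), inertia=meta["inertia"],
                        distances=table["distance"].to_numpy(dtype=float), seed=meta["seed"],
                        n_init=meta["n_init"], max_iter=meta["max_iter"], tol=meta["tol"],
                        slide_id=meta["slide_id"])
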