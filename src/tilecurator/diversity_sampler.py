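"""Distance-binned diversity sampling — the curation step this package exists for.

Sampling tiles nearest their cluster centroid over-represents the dense,
homogeneous core of each morphologic cluster. Instead, per cluster the
centroid distances are min-max normalized to [0, 1], tiles are sorted by
distance, partitioned into ``g`` equal-frequency bins (default 5; sizes
differ by at most one, with the larger bins at the low-distance end), and a
fixed fraction (default 20%) of each bin is sampled uniformly without
replacement. Every bin — from near-centroid prototypes to edge-of-cluster
variants — contributes, so the sample spans the cluster's full morphologic
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .embedding import EmbeddingMatrix

DEFAULT_G = 5
DEFAULT_FRACTION = 0.2


@dataclass
class BinAssignment:
    cluster_index: int
    tile_ids: list[str]          # sorted by (normalized distance, tile_id)
    normalized: np.ndarray       # (n,) in [0, 1], same order as tile_ids
    bins: np.ndarray             # (n,) bin index in {0, ..., g-1}
    g: int

    def bin_tile_ids(self, b: int) -> list[str]:
        return [t for t, bb in zip(self.tile_ids, self.bins) if bb == b]

    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bins, minlength=self.g)


@dataclass
class DiversitySample:
    cluster_index: int
    sampled_tile_ids: list[str]
    per_bin_counts: dict[int, int]
    bin_of_tile: dict[str, int]       # bin provenance for every tile in the cluster
    normalized_of_tile: dict[str, float]
    fraction: float
    seed: int


def normalize_distances(distances: np.ndarray) -> np.ndarray:
    """Per-cluster min-max scaling to [0, 1]; an all-equal cluster maps to 0."""
    d = np.asarray(distances, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one distance")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    lo, hi = d.min(), d.max()
    if hi == lo:
        return np.zeros_like(d)
    return (d - lo) / (hi - lo)


def equal_frequency_bins(tile_ids: list[str], normalized: np.ndarray, g: int = DEFAULT_G,
                         cluster_index: int = 0) -> BinAssignment:
    """Split distance-sorted tiles into ``g`` contiguous near-equal bins.

    Sorting is stable on (normalized distance, tile_id) so ties are
    reproducible. With ``n = q*g + r`` the first ``r`` bins (lowest
    distances) hold ``q + 1`` tiles and the rest hold ``q``; sizes therefore
    differ by at most one. Fewer tiles than bins leaves the trailing bins
    empty.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    n = len(tile_ids)
    if n < 1 or len(normalized) != n:
        raise ValueError("tile_ids and normalized distances must be non-empty and aligned")
    order = sorted(range(n), key=lambda i: (normalized[i], tile_ids[i]))
    sorted_ids = [tile_ids[i] for i in order]
    sorted_norm = np.asarray(normalized, dtype=float)[order]
    q, r = divmod(n, g)
    bins = np.empty(n, dtype=np.int64)
    start = 0
    for b in range(g):
        size = q + 1 if b < r else q
        bins[start : start + size] = b
        start += size
    return BinAssignment(cluster_index=cluster_index, tile_ids=sorted_ids,
                         normalized=sorted_norm, bins=bins, g=g)


def sample_bins(bins: BinAssignment, fraction: float = DEFAULT_FRACTION,
                seed: int = 0) -> DiversitySample:
    """Sample ``max(1, round(f * |bin|))`` tiles uniformly from each non-empty bin."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sampled: list[str] = []
    per_bin: dict[int, int] = {}
    for b in range(bins.g):
        members = bins.bin_tile_ids(b)
        if not members:
            continue
        count = max(1, int(np.floor(fraction * len(members) + 0.5)))
        count = min(count, len(members))
        pick = rng.choice(len(members), size=count, replace=False)
        sampled.extend(members[i] for i in sorted(pick))
        per_bin[b] = count
    return DiversitySample(
        cluster_index=bins.cluster_index,
        sampled_tile_ids=sampled,
        per_bin_counts=per_bin,
        bin_of_tile={t: int(b) for t, b in zip(bins.tile_ids, bins.bins)},
        normalized_of_tile={t: float(v) for t, v in zip(bins.tile_ids, bins.normalized)},
        fraction=fraction,
        seed=seed,
    )


def sample_cluster(reduced: EmbeddingMatrix, model: ClusterModel, cluster_index: int,
                   g: int = DEFAULT_G, fraction: float = DEFAULT_FRACTION,
                   seed: int = 0) -> DiversitySample:
    """normalize -> equal-frequency bin -> per-bin sample for one cluster."""
    members = model.cluster_tile_ids(cluster_index)
    if not members:
        raise KeyError(f"cluster {cluster_index} is empty or unknown")
    index_of = {t: i for i, t in enumerate(model.tile_ids)}
    dists = np.array([model.distances[index_of[t]] for t in members])
    normalized = normalize_distances(dists)
    bins = equal_frequency_bins(members, normalized, g=g, cluster_index=cluster_index)
    return sample_bins(bins, fraction=fraction, seed=seed)


def sample_all_clusters(reduced: EmbeddingMatrix, model: ClusterModel, g: int = DEFAULT_G,
                        fraction: float = DEFAULT_FRACTION, seed: int = 0) -> list[DiversitySample]:
    """Diversity sample for every cluster; per-cluster seeds derived from ``seed``."""
    return [sample_cluster(reduced, model, c, g=g, fraction=fraction,
                           seed=(seed + 7919 * c) % 2 ** 31) for c in range(model.K)]


def samples_to_manifest(samples: list[DiversitySample], model: ClusterModel) -> pd.DataFrame:
    """Audit manifest: every cluster tile with its bin, normalized distance, and
    ``selected`` in {0, 1}."""
    rows = []
    for s in samples:
        chosen = set(s.sampled_tile_ids)
        for tile_id in sorted(s.bin_of_tile):
            rows.append({
                "tile_id": tile_id,
                "slide_id": model.slide_id,
                "cluster": s.cluster_index,
                "bin": s.bin_of_tile[tile_id],
                "distance_norm": s.normalized_of_tile[tile_id],
                "selected": int(tile_id in chosen),
            })
    return pd.DataFrame(rows, columns=["tile_id", "slide_id", "cluster", "bin", "distance_norm", "selected"])


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False, float_format="%.8f")
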