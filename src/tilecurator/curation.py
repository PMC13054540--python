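"""Review scaffolding: cluster labels, propagation, QuPath export, assembly.

Clusters carry no semantic labels after K-means, so a reviewer labels a seed
cluster with a tissue class and the label is propagated as a *proposal* to
the nearest unlabeled clusters in embedding space (nearby clusters tend to
share morphology). Proposals stay proposals until confirmed; only confirmed
tiles may enter the final per-class dataset, which caps every class at a
fixed count (70,000 at full scale) by seeded uniform subsampling. Sampled
tiles are exported as QuPath-compatible GeoJSON rectangles in level-0 slide
pixel coordinates so the reviewer sees each tile in its original context.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel, neighbor_clusters

DEFAULT_CLASSES = ("ADI", "LYM", "MUS", "FCT", "MUC", "NCS", "BLD", "TUM", "NOR")
DEFAULT_PER_CLASS_CAP = 70_000

MANIFEST_COLUMNS = ["tile_id", "slide_id", "x", "y", "width", "height", "class",
                    "cluster", "bin", "distance_norm", "review_status"]


@dataclass
class ClusterLabel:
    slide_id: str
    cluster: int
    class_name: str
    source: str  # seed | propagated | confirmed | rejected
    seed_cluster: int | None = None
    neighbor_rank: int | None = None


class LabelBook:
    """Label state machine for one slide's clusters.

    A cluster has at most one non-rejected label. Seed and confirmed labels
    are authoritative; propagated labels are proposals and may be confirmed,
    rejected, or silently superseded by nothing — they never overwrite a seed
    or confirmed label.
    """

    def __init__(self, slide_id: str, classes: tuple[str, ...] = DEFAULT_CLASSES):
        self.slide_id = slide_id
        self.classes = tuple(classes)
        self._labels: dict[int, ClusterLabel] = {}

    def label_of(self, cluster: int) -> ClusterLabel | None:
        lbl = self._labels.get(cluster)
        return None if lbl is None or lbl.source == "rejected" else lbl

    def active_labels(self) -> list[ClusterLabel]:
        return [l for l in self._labels.values() if l.source != "rejected"]

    def assign_seed_label(self, cluster: int, class_name: str) -> ClusterLabel:
        if class_name not in self.classes:
            raise ValueError(f"unknown class {class_name!r}; vocabulary is {self.classes}")
        existing = self.label_of(cluster)
        if existing is not None and not (existing.class_name == class_name and existing.source == "seed"):
            raise ValueError(
                f"cluster {cluster} already labeled {existing.class_name!r} "
                f"(source={existing.source}); reject it before relabeling as {class_name!r}"
            )
        label = ClusterLabel(self.slide_id, cluster, class_name, "seed")
        self._labels[cluster] = label
        return label

    def confirm(self, cluster: int) -> ClusterLabel:
        lbl = self.label_of(cluster)
        if lbl is None:
            raise KeyError(f"cluster {cluster} has no active label to confirm")
        lbl.source = "confirmed"
        return lbl

    def reject(self, cluster: int) -> None:
        if cluster in self._labels:
            self._labels[cluster].source = "rejected"

    def add_proposal(self, label: ClusterLabel) -> None:
        if self.label_of(label.cluster) is None:
            self._labels[label.cluster] = label


def propagate_labels(model: ClusterModel, book: LabelBook, n_neighbors: int = 4,
                     distance_cap: float = np.inf) -> list[ClusterLabel]:
    """Propose each seed's class for its nearest unlabeled clusters.

    For every seed (or confirmed) label, the ``n_neighbors`` nearest clusters
    within ``distance_cap`` receive the seed's class as a proposal with the
    neighbor rank recorded. When two seeds reach the same cluster, the seed
    with the smaller centroid distance wins; exact ties go to the smaller
    seed cluster index. Proposals never overwrite seed or confirmed labels.
    """
    seeds = sorted((l for l in book.active_labels() if l.source in ("seed", "confirmed")),
                   key=lambda l: l.cluster)
    if not seeds:
        raise ValueError("need at least one seed label to propagate")
    # candidate (distance, seed_cluster, rank, class) per target cluster
    best: dict[int, tuple[float, int, int, str]] = {}
    for seed in seeds:
        for rank, (nbr, dist) in enumerate(neighbor_clusters(model, seed.cluster, n_neighbors)):
            if dist > distance_cap or book.label_of(nbr) is not None:
                continue
            cand = (dist, seed.cluster, rank, seed.class_name)
            if nbr not in best or cand < best[nbr]:
                best[nbr] = cand
    proposals = []
    for nbr in sorted(best):
        dist, seed_cluster, rank, class_name = best[nbr]
        label = ClusterLabel(book.slide_id, nbr, class_name, "propagated",
                             seed_cluster=seed_cluster, neighbor_rank=rank)
        book.add_proposal(label)
        proposals.append(label)
    return proposals


def build_manifest(sample_manifest: pd.DataFrame, tile_table: pd.DataFrame,
                   book: LabelBook, selected_only: bool = True) -> pd.DataFrame:
    """Join sampled tiles with coordinates and cluster labels into a review manifest.

    ``sample_manifest`` is the diversity sampler's audit table; ``tile_table``
    carries tile_id -> (slide_id, x, y, width, height). Tiles in unlabeled
    clusters are dropped (nothing to review). review_status starts as
    'proposed' for propagated labels and 'confirmed' for confirmed ones;
    seeds count as proposed until confirmed.
    """
    coords = tile_table.set_index("tile_id")
    rows = []
    source = sample_manifest[sample_manifest["selected"] == 1] if selected_only else sample_manifest
    for row in source.itertuples(index=False):
        lbl = book.label_of(int(row.cluster))
        if lbl is None:
            continue
        tc = coords.loc[row.tile_id]
        rows.append({
            "tile_id": row.tile_id, "slide_id": row.slide_id,
            "x": int(tc["x"]), "y": int(tc["y"]),
            "width": int(tc["width"]), "height": int(tc["height"]),
            "class": lbl.class_name, "cluster": int(row.cluster), "bin": int(row.bin),
            "distance_norm": float(row.distance_norm),
            "review_status": "confirmed" if lbl.source == "confirmed" else "proposed",
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["tile_id"].duplicated().any():
        raise ValueError("tile_ids in a curation manifest must be unique")
    return manifest


def export_qupath_annotations(manifest: pd.DataFrame, slide_width: int, slide_height: int) -> dict:
    """GeoJSON FeatureCollection of tile rectangles for QuPath.

    One closed, counter-clockwise rectangle ring per tile in level-0 pixel
    coordinates, with ``classification.name`` and ``tile_id`` properties.
    """
    offenders = [
        row.tile_id for row in manifest.itertuples(index=False)
        if row.x < 0 or row.y < 0 or row.x + row.width > slide_width or row.y + row.height > slide_height
    ]
    if offenders:
        raise ValueError(f"tiles outside slide bounds {slide_width}x{slide_height}: {offenders}")
    features = []
    for row in manifest.to_dict("records"):
        x0, y0 = float(row["x"]), float(row["y"])
        x1, y1 = x0 + row["width"], y0 + row["height"]
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"classification": {"name": row["class"]}, "tile_id": row["tile_id"]},
        })
    return {"type": "FeatureCollection", "features": features}


def write_qupath_annotations(manifest: pd.DataFrame, slide_width: int, slide_height: int,
                             path: str | Path) -> None:
    doc = export_qupath_annotations(manifest, slide_width, slide_height)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc, indent=2))
    # plain CSV coordinate export for tools that do not read GeoJSON
    manifest[["tile_id", "slide_id", "x", "y", "width", "height", "class"]].to_csv(
        Path(path).with_suffix(".csv"), index=False)


def assemble_dataset(manifests: list[pd.DataFrame], tile_dirs: list[str | Path],
                     out_dir: str | Path, per_class_cap: int = DEFAULT_PER_CLASS_CAP,
                     seed: int = 0) -> pd.DataFrame:
    """Copy confirmed tiles into ``out_dir/<CLASS>/`` with a per-class cap.

    Every manifest row must have review_status 'confirmed' (verification is
    mandatory before assembly). A class exceeding the cap is reduced to
    exactly ``per_class_cap`` tiles by a seeded uniform subsample over the
    tile_ids sorted lexicographically, so assembly is idempotent for a fixed
    seed. Returns the summary table ``class,count`` (also written to
    ``summary.csv``).
    """
    combined = pd.concat(manifests, ignore_index=True) if manifests else pd.DataFrame(columns=MANIFEST_COLUMNS)
    unconfirmed = combined[combined["review_status"] != "confirmed"]
    if len(unconfirmed):
        raise ValueError(
            f"{len(unconfirmed)} tiles are not confirmed (e.g. {unconfirmed['tile_id'].iloc[0]}); "
            "review must be completed before assembly"
        )
    if combined["tile_id"].duplicated().any():
        raise ValueError("a tile may not appear twice in the assembled dataset")

    tile_dirs = [Path(d) for d in tile_dirs]

    def locate(tile_id: str) -> Path:
        for d in tile_dirs:
            p = d / f"{tile_id}.png"
            if p.exists():
                return p
        raise FileNotFoundError(f"tile raster {tile_id}.png not found in {tile_dirs}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = []
    for class_name, group in combined.groupby("class", sort=True):
        ids = sorted(group["tile_id"])
        if len(ids) > per_class_cap:
            rng = np.random.default_rng((seed, hash_class(class_name)))
            keep = rng.choice(len(ids), size=per_class_cap, replace=False)
            ids = [ids[i] for i in sorted(keep)]
        class_dir = out_dir / class_name
        class_dir.mkdir(exist_ok=True)
        for tile_id in ids:
            shutil.copyfile(locate(tile_id), class_dir / f"{tile_id}.png")
        summary.append({"class": class_name, "count": len(ids)})
    table = pd.DataFrame(summary, columns=["class", "count"])
    table.to_csv(out_dir / "summary.csv", index=False)
    return table


def hash_class(class_name: str) -> int:
    """Stable small hash so per-class subsampling seeds don't depend on PYTHONHASHSEED."""
    return sum((i + 1) * ord(c) for i, c in enumerate(class_name)) % 100_003
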