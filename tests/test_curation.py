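"""Label state machine, propagation, QuPath GeoJSON export, dataset assembly."""

import json

import numpy as np
import pandas as pd
import pytest

from tilecurator.clustering import ClusterModel
from tilecurator.curation import (
    DEFAULT_CLASSES,
    LabelBook,
    assemble_dataset,
    build_manifest,
    export_qupath_annotations,
    propagate_labels,
    write_qupath_annotations,
)

MANIFEST_COLUMNS = ["tile_id", "slide_id", "x", "y", "width", "height", "class",
                    "cluster", "bin", "distance_norm", "review_status"]


def model_with_centroids(centroids):
    centroids = np.asarray(centroids, dtype=float)
    k = len(centroids)
    return ClusterModel(K=k, centroids=centroids, tile_ids=[f"t{i}" for i in range(k)],
                        labels=np.arange(k), inertia=0.0, distances=np.zeros(k),
                        seed=0, n_init=1, max_iter=1, tol=0.0, slide_id="s")


def manifest_row(tile_id, x=0, y=0, cls="TUM", status="confirmed", cluster=0):
    return {"tile_id": tile_id, "slide_id": "s", "x": x, "y": y, "width": 256, "height": 256,
            "class": cls, "cluster": cluster, "bin": 0, "distance_norm": 0.5,
            "review_status": status}


class TestLabelBook:
    def test_seed_label_recorded(self):
        book = LabelBook("s")
        lbl = book.assign_seed_label(48, "TUM")
        assert lbl.source == "seed" and book.label_of(48).class_name == "TUM"

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            LabelBook("s").assign_seed_label(0, "XYZ")

    def test_conflicting_label_reported_with_both(self):
        book = LabelBook("s")
        book.assign_seed_label(1, "TUM")
        with pytest.raises(ValueError) as err:
            book.assign_seed_label(1, "NOR")
        assert "TUM" in str(err.value) and "NOR" in str(err.value)

    def test_relabel_after_reject_allowed(self):
        book = LabelBook("s")
        book.assign_seed_label(1, "TUM")
        book.reject(1)
        assert book.label_of(1) is None
        book.assign_seed_label(1, "NOR")
        assert book.label_of(1).class_name == "NOR"

    def test_confirm_requires_active_label(self):
        with pytest.raises(KeyError):
            LabelBook("s").confirm(3)


class TestPropagation:
    def test_all_neighbors_beyond_cap_yields_no_proposals(self):
        model = model_with_centroids([[0.0], [100.0], [200.0]])
        book = LabelBook("s")
        book.assign_seed_label(0, "TUM")
        assert propagate_labels(model, book, n_neighbors=2, distance_cap=10.0) == []

    def test_nearest_unlabeled_clusters_receive_proposals(self):
        model = model_with_centroids([[0.0], [1.0], [2.0], [50.0]])
        book = LabelBook("s")
        book.assign_seed_label(0, "TUM")
        props = propagate_labels(model, book, n_neighbors=2)
        assert {(p.cluster, p.class_name, p.source) for p in props} == {
            (1, "TUM", "propagated"), (2, "TUM", "propagated")}
        assert all(p.seed_cluster == 0 for p in props)

    def test_closer_seed_wins_contested_neighbor(self):
        # cluster 1 sits between seeds 0 (distance 1) and 2 (distance 2)
        model = model_with_centroids([[0.0], [1.0], [3.0]])
        book = LabelBook("s")
        book.assign_seed_label(0, "TUM")
        book.assign_seed_label(2, "NOR")
        props = propagate_labels(model, book, n_neighbors=1)
        assert len(props) == 1 and props[0].cluster == 1 and props[0].class_name == "TUM"

    def test_exact_tie_goes_to_smaller_seed_index(self):
        model = model_with_centroids([[0.0], [1.0], [2.0]])
        book = LabelBook("s")
        book.assign_seed_label(0, "TUM")
        book.assign_seed_label(2, "NOR")
        props = propagate_labels(model, book, n_neighbors=1)
        assert props[0].cluster == 1 and props[0].class_name == "TUM"

    def test_proposals_never_overwrite_seed_or_confirmed(self):
        model = model_with_centroids([[0.0], [1.0]])
        book = LabelBook("s")
        book.assign_seed_label(0, "TUM")
        book.assign_seed_label(1, "NOR")
        book.confirm(1)
        propagate_labels(model, book, n_neighbors=1)
        assert book.label_of(1).class_name == "NOR"
        assert book.label_of(1).source == "confirmed"

    def test_requires_a_seed(self):
        with pytest.raises(ValueError, match="seed"):
            propagate_labels(model_with_centroids([[0.0], [1.0]]), LabelBook("s"))


class TestQuPathExport:
    def test_rectangle_ring_coordinates(self):
        manifest = pd.DataFrame([manifest_row("s_512_768", x=512, y=768)])
        doc = export_qupath_annotations(manifest, 2048, 2048)
        ring = doc["features"][0]["geometry"]["coordinates"][0]
        assert ring == [[512, 768], [768, 768], [768, 1024], [512, 1024], [512, 768]]
        assert doc["features"][0]["properties"]["classification"]["name"] == "TUM"

    def test_empty_manifest_empty_collection(self):
        doc = export_qupath_annotations(pd.DataFrame(columns=MANIFEST_COLUMNS), 1024, 1024)
        assert doc == {"type": "FeatureCollection", "features": []}

    def test_round_trip_feature_count(self, tmp_path):
        manifest = pd.DataFrame([manifest_row(f"s_{x}_0", x=x) for x in (0, 256, 512)])
        path = tmp_path / "ann.geojson"
        write_qupath_annotations(manifest, 1024, 256, path)
        parsed = json.loads(path.read_text())
        assert len(parsed["features"]) == len(manifest)
        csv = pd.read_csv(path.with_suffix(".csv"))
        assert len(csv) == len(manifest)

    def test_out_of_bounds_tiles_listed(self):
        manifest = pd.DataFrame([manifest_row("s_900_0", x=900)])
        with pytest.raises(ValueError, match="s_900_0"):
            export_qupath_annotations(manifest, 1024, 1024)

    def test_rings_closed_and_ccw(self):
        from shapely.geometry import shape

        manifest = pd.DataFrame([manifest_row("s_0_0"), manifest_row("s_256_0", x=256)])
        doc = export_qupath_annotations(manifest, 1024, 1024)
        for feat in doc["features"]:
            ring = feat["geometry"]["coordinates"][0]
            assert ring[0] == ring[-1]
            assert shape(feat["geometry"]).exterior.is_ccw


def write_fake_tiles(directory, tile_ids):
    import imageio.v3 as iio

    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(0)
    for t in tile_ids:
        iio.imwrite(directory / f"{t}.png",
                    rng.integers(0, 255, size=(8, 8, 3)).astype(np.uint8), extension=".png")


class TestAssembly:
    def make_manifest(self, counts, status="confirmed"):
        rows = []
        for cls, n in counts.items():
            for i in range(n):
                rows.append(manifest_row(f"s_{cls}_{i}", cls=cls, status=status))
        return pd.DataFrame(rows)

    def test_per_class_cap_applied(self, tmp_path):
        manifest = self.make_manifest({"TUM": 120, "NOR": 80, "LYM": 50})
        tiles_dir = tmp_path / "tiles"
        write_fake_tiles(tiles_dir, manifest["tile_id"])
        summary = assemble_dataset([manifest], [tiles_dir], tmp_path / "out", per_class_cap=100, seed=0)
        got = dict(zip(summary["class"], summary["count"]))
        assert got == {"TUM": 100, "NOR": 80, "LYM": 50}
        # directory count oracle
        for cls, n in got.items():
            assert len(list((tmp_path / "out" / cls).glob("*.png"))) == n

    def test_cap_larger_than_classes_changes_nothing(self, tmp_path):
        manifest = self.make_manifest({"TUM": 5, "NOR": 3})
        tiles_dir = tmp_path / "tiles"
        write_fake_tiles(tiles_dir, manifest["tile_id"])
        summary = assemble_dataset([manifest], [tiles_dir], tmp_path / "out", per_class_cap=1000, seed=0)
        assert dict(zip(summary["class"], summary["count"])) == {"TUM": 5, "NOR": 3}

    def test_unconfirmed_tiles_rejected(self, tmp_path):
        manifest = self.make_manifest({"TUM": 3}, status="proposed")
        with pytest.raises(ValueError, match="confirmed"):
            assemble_dataset([manifest], [tmp_path], tmp_path / "out")

    def test_duplicate_tile_across_classes_rejected(self, tmp_path):
        a = pd.DataFrame([manifest_row("dup", cls="TUM")])
        b = pd.DataFrame([manifest_row("dup", cls="NOR")])
        with pytest.raises(ValueError, match="twice"):
            assemble_dataset([a, b], [tmp_path], tmp_path / "out")

    def test_assembly_idempotent_for_fixed_seed(self, tmp_path):
        manifest = self.make_manifest({"TUM": 30})
        tiles_dir = tmp_path / "tiles"
        write_fake_tiles(tiles_dir, manifest["tile_id"])
        s1 = assemble_dataset([manifest], [tiles_dir], tmp_path / "o1", per_class_cap=10, seed=4)
        s2 = assemble_dataset([manifest], [tiles_dir], tmp_path / "o2", per_class_cap=10, seed=4)
        assert sorted(p.name for p in (tmp_path / "o1" / "TUM").iterdir()) == \
               sorted(p.name for p in (tmp_path / "o2" / "TUM").iterdir())
        assert s1.equals(s2)


def test_build_manifest_joins_labels_and_coordinates():
    book = LabelBook("s")
    book.assign_seed_label(0, "TUM")
    book.confirm(0)
    book.assign_seed_label(1, "NOR")  # seed, not confirmed -> proposed
    sample_manifest = pd.DataFrame([
        {"tile_id": "s_0_0", "slide_id": "s", "cluster": 0, "bin": 2, "distance_norm": 0.4, "selected": 1},
        {"tile_id": "s_256_0", "slide_id": "s", "cluster": 1, "bin": 0, "distance_norm": 0.1, "selected": 1},
        {"tile_id": "s_512_0", "slide_id": "s", "cluster": 2, "bin": 1, "distance_norm": 0.9, "selected": 1},
        {"tile_id": "s_768_0", "slide_id": "s", "cluster": 0, "bin": 1, "distance_norm": 0.2, "selected": 0},
    ])
    tile_table = pd.DataFrame([
        {"tile_id": f"s_{x}_0", "slide_id": "s", "x": x, "y": 0, "width": 256, "height": 256}
        for x in (0, 256, 512, 768)
    ])
    manifest = build_manifest(sample_manifest, tile_table, book)
    assert list(manifest.columns) == MANIFEST_COLUMNS
    # unlabeled cluster 2 dropped, unselected tile dropped
    assert set(manifest["tile_id"]) == {"s_0_0", "s_256_0"}
    by_tile = manifest.set_index("tile_id")
    assert by_tile.loc["s_0_0", "review_status"] == "confirmed"
    assert by_tile.loc["s_256_0", "review_status"] == "proposed"
    assert by_tile.loc["s_0_0", "class"] == "TUM"


def test_default_class_vocabulary_has_nine_tissue_types():
    assert len(DEFAULT_CLASSES) == 9 and len(set(DEFAULT_CLASSES)) == 9
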