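"""Stage orchestration: run the curation pipeline end to end on a work directory.

Stages (in order): synth -> tile -> train-ae -> embed -> cluster -> sample ->
export -> assemble. Each stage reads the previous stage's outputs from the
work directory, writes its own outputs, and drops a JSON run record (config
hash, seed, inputs/outputs, counts) under ``records/``, so the tile funnel
(extracted -> QC-passed -> clustered -> sampled -> assembled) can be audited.
Re-running a stage with the same config and inputs reproduces its outputs.

The export stage needs tissue-class labels for clusters. On synthetic slides
the ground-truth mask is available, so the pipeline labels each cluster with
the majority ground-truth texture of its member tiles and marks the labels
confirmed — a machine stand-in for the human review sign-off, which keeps
the full pipeline runnable unattended. With real slides the LabelBook in
:mod:`tilecurator.curation` is driven interactively instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, curation, diversity_sampler, embedding, synthetic_slide, tiling
from .autoencoder import Autoencoder, EncoderConfig, save_training_curve, train_autoencoder
from .config import STAGES, PipelineConfig


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' requires {path.name} produced by stage '{stage}'; run that stage first"
        )
    return path


def _record(workdir: Path, stage: str, config: PipelineConfig, seed: int,
            inputs: list[str], outputs: list[str], counts: dict[str, int]) -> None:
    rec_dir = workdir / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    record = {"stage": stage, "config_hash": config.config_hash(), "seed": seed,
              "inputs": inputs, "outputs": outputs, "counts": counts}
    (rec_dir / f"{stage}.json").write_text(json.dumps(record, indent=2))


def _encoder_config(config: PipelineConfig) -> EncoderConfig:
    enc = EncoderConfig()
    return enc if config.ae_width_factor == 1 else enc.reduced(config.ae_width_factor)


def run_stage(stage: str, config: PipelineConfig, workdir: str | Path) -> dict:
    """Run one named stage; returns its run-record counts."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; stages are {STAGES}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed(stage)
    counts: dict[str, int] = {}

    if stage == "synth":
        spec = synthetic_slide.quadrant_slide_spec(
            side=config.synth_side, region_side=config.synth_region_side,
            margin=config.synth_margin, seed=seed, slide_id="synthetic")
        slide = synthetic_slide.generate_slide(spec)
        synthetic_slide.write_slide(slide, workdir / "slide")
        counts = {"width": spec.width, "height": spec.height, "regions": len(spec.regions)}
        _record(workdir, stage, config, seed, [], ["slide/image.tiff", "slide/mask.png", "slide/spec.json"], counts)

    elif stage == "tile":
        slide_dir = _require(workdir / "slide", "synth", stage)
        slide = synthetic_slide.read_slide(slide_dir)
        mask = tiling.compute_tissue_mask(slide.image, downsample=config.downsample)
        extracted = tiling.extract_tiles(slide.image, mask, tile_size=config.tile_size,
                                         tissue_threshold=config.tissue_threshold,
                                         slide_id=slide.spec.slide_id)
        retained, flagged = tiling.filter_artifacts(extracted, slide.image)
        tiling.write_tiles(retained, slide.image, workdir / "tiles")
        counts = {"grid_tiles": (slide.image.shape[0] // config.tile_size)
                  * (slide.image.shape[1] // config.tile_size),
                  "tissue_tiles": len(extracted), "qc_flagged": len(flagged), "retained": len(retained)}
        _record(workdir, stage, config, seed, ["slide/"], ["tiles/"], counts)

    elif stage == "train-ae":
        tiles_dir = _require(workdir / "tiles" / "manifest.csv", "tile", stage).parent
        records, rasters = tiling.read_tiles(tiles_dir)
        if not records:
            raise PipelineError("no retained tiles to train on")
        model, state = train_autoencoder(
            rasters, enc=_encoder_config(config), epochs=config.ae_epochs,
            batch_size=config.ae_batch_size, learning_rate=config.ae_learning_rate, seed=seed)
        model.save(workdir / "ae" / "checkpoint.npz")
        save_training_curve(state, workdir / "ae" / "curve.csv")
        counts = {"tiles": len(records), "epochs": state.epochs}
        _record(workdir, stage, config, seed, ["tiles/"], ["ae/checkpoint.npz", "ae/curve.csv"], counts)

    elif stage == "embed":
        ckpt = _require(workdir / "ae" / "checkpoint.npz", "train-ae", stage)
        tiles_dir = _require(workdir / "tiles" / "manifest.csv", "tile", stage).parent
        model = Autoencoder.load(ckpt)
        records, rasters = tiling.read_tiles(tiles_dir)
        latent = embedding.encode_tiles(model, rasters, [r.tile_id for r in records],
                                        slide_id=records[0].slide_id if records else "slide")
        enc = model.enc_config
        pooled = embedding.global_average_pool(
            latent, (enc.final_channels, enc.final_spatial, enc.final_spatial))
        pca = embedding.fit_pca(pooled, n_components=config.pca_components)
        reduced = embedding.apply_pca(pca, pooled)
        for em, name in ((latent, "latent"), (pooled, "pooled"), (reduced, "reduced")):
            embedding.save_embedding(em, workdir / "embeddings" / name)
        counts = {"tiles": latent.n, "latent_dim": latent.dim, "pooled_dim": pooled.dim,
                  "reduced_dim": reduced.dim}
        _record(workdir, stage, config, seed, ["tiles/", "ae/"], ["embeddings/"], counts)

    elif stage == "cluster":
        reduced = embedding.load_embedding(
            _require(workdir / "embeddings" / "reduced.npy", "embed", stage).with_suffix(""))
        k = clustering.choose_k(reduced.n, config.m)
        model = clustering.kmeans(reduced, K=k, seed=seed, n_init=config.n_init,
                                  max_iter=config.max_iter, tol=config.tol)
        clustering.save_cluster_model(model, workdir / "cluster" / "model")
        counts = {"tiles": reduced.n, "K": model.K, "inertia_x1000": int(model.inertia * 1000)}
        _record(workdir, stage, config, seed, ["embeddings/"], ["cluster/"], counts)

    elif stage == "sample":
        model = clustering.load_cluster_model(
            _require(workdir / "cluster" / "model.json", "cluster", stage).with_suffix(""))
        reduced = embedding.load_embedding(
            _require(workdir / "embeddings" / "reduced.npy", "embed", stage).with_suffix(""))
        samples = diversity_sampler.sample_all_clusters(
            reduced, model, g=config.g, fraction=config.sample_fraction, seed=seed)
        manifest = diversity_sampler.samples_to_manifest(samples, model)
        diversity_sampler.write_manifest(manifest, workdir / "samples" / "sample_manifest.csv")
        counts = {"clusters": model.K, "tiles": len(manifest),
                  "sampled": int(manifest["selected"].sum())}
        _record(workdir, stage, config, seed, ["cluster/", "embeddings/"], ["samples/"], counts)

    elif stage == "export":
        sample_path = _require(workdir / "samples" / "sample_manifest.csv", "sample", stage)
        model = clustering.load_cluster_model(
            _require(workdir / "cluster" / "model.json", "cluster", stage).with_suffix(""))
        tile_manifest = pd.read_csv(
            _require(workdir / "tiles" / "manifest.csv", "tile", stage), keep_default_na=False)
        slide = synthetic_slide.read_slide(_require(workdir / "slide", "synth", stage))
        sample_manifest = pd.read_csv(sample_path)

        book = _auto_label_clusters(model, slide, tile_manifest, config)
        manifest = curation.build_manifest(sample_manifest, tile_manifest, book)
        curation.write_qupath_annotations(manifest, slide.spec.width, slide.spec.height,
                                          workdir / "export" / "annotations.geojson")
        manifest.to_csv(workdir / "export" / "curation_manifest.csv", index=False, float_format="%.8f")
        counts = {"labeled_clusters": len(book.active_labels()), "tiles": len(manifest)}
        _record(workdir, stage, config, seed, ["samples/", "cluster/", "tiles/", "slide/"],
                ["export/"], counts)

    elif stage == "assemble":
        manifest = pd.read_csv(
            _require(workdir / "export" / "curation_manifest.csv", "export", stage),
            keep_default_na=False)
        summary = curation.assemble_dataset([manifest], [workdir / "tiles"], workdir / "dataset",
                                            per_class_cap=config.per_class_cap, seed=seed)
        counts = {row["class"]: int(row["count"]) for _, row in summary.iterrows()}
        _record(workdir, stage, config, seed, ["export/", "tiles/"], ["dataset/"], counts)

    return counts


def _auto_label_clusters(model: clustering.ClusterModel, slide: synthetic_slide.SyntheticSlide,
                         tile_manifest: pd.DataFrame, config: PipelineConfig) -> curation.LabelBook:
    """Label every cluster with the majority ground-truth texture of its tiles,
    then confirm — the synthetic-slide stand-in for the pathologist review."""
    gt = synthetic_slide.tile_ground_truth(slide, tile_size=config.tile_size)
    gt_label = {(int(r.x), int(r.y)): int(r.majority_label) for r in gt.itertuples(index=False)}
    coords = {r.tile_id: (int(r.x), int(r.y)) for r in tile_manifest.itertuples(index=False)}
    book = curation.LabelBook(model.slide_id, classes=config.classes)
    for c in range(model.K):
        members = model.cluster_tile_ids(c)
        texture_votes = np.array([gt_label[coords[t]] for t in members if coords[t] in gt_label])
        if texture_votes.size == 0:
            continue
        majority = int(np.bincount(texture_votes).argmax())
        if majority == 0:
            continue  # background-dominated cluster: leave unlabeled
        class_name = config.classes[(majority - 1) % len(config.classes)]
        book.assign_seed_label(c, class_name)
        book.confirm(c)
    return book


def run_all(config: PipelineConfig, workdir: str | Path) -> dict[str, dict]:
    """Run every stage in order; returns the per-stage counts."""
    return {stage: run_stage(stage, config, workdir) for stage in STAGES}
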