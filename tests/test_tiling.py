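"""Tissue masking, grid tile extraction and QC filtering."""

import numpy as np
import pytest
from skimage.color import rgb2hsv
from skimage.measure import block_reduce

from tilecurator.synthetic_slide import (
    Region,
    SlideSpec,
    default_texture_palette,
    generate_slide,
)
from tilecurator.tiling import (
    TileRecord,
    compute_tissue_mask,
    extract_tiles,
    filter_artifacts,
    manifest_to_records,
    qc_flags_for_tile,
    read_tiles,
    records_to_manifest,
    write_tiles,
)


def half_covered_slide():
    tex = default_texture_palette()[:1]
    spec = SlideSpec(width=1024, height=1024, textures=tex,
                     regions=[Region(texture_id=1, rect=(0, 0, 1024, 512))], seed=9)
    return generate_slide(spec)


def full_covered_slide():
    tex = default_texture_palette()[:1]
    spec = SlideSpec(width=1024, height=1024, textures=tex,
                     regions=[Region(texture_id=1, rect=(0, 0, 1024, 1024))], seed=9)
    return generate_slide(spec)


class TestTissueMask:
    def test_uniform_near_white_has_no_tissue(self):
        image = np.full((1024, 1024, 3), 245, dtype=np.uint8)
        mask = compute_tissue_mask(image)
        assert mask.mask.sum() == 0

    def test_mask_dimensions_at_downsample_32(self):
        mask = compute_tissue_mask(np.full((1024, 1024, 3), 245, dtype=np.uint8), downsample=32)
        assert mask.mask.shape == (32, 32)

    def test_half_covered_slide_mask_fraction(self):
        slide = half_covered_slide()
        mask = compute_tissue_mask(slide.image)
        frac = mask.mask.mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_mask_matches_per_pixel_thresholding_at_recorded_value(self):
        # independent oracle: block-average, HSV, threshold pixelwise at threshold_value
        slide = half_covered_slide()
        mask = compute_tissue_mask(slide.image, downsample=32)
        small = block_reduce(slide.image.astype(np.float32), (32, 32, 1), np.mean)
        sat = rgb2hsv(small / 255.0)[:, :, 1]
        oracle = np.zeros_like(sat, dtype=np.uint8)
        for i in range(sat.shape[0]):
            for j in range(sat.shape[1]):
                oracle[i, j] = 1 if sat[i, j] > mask.threshold_value else 0
        np.testing.assert_array_equal(mask.mask, oracle)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            compute_tissue_mask(np.zeros((16, 16, 3), dtype=np.uint8), downsample=32)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            compute_tissue_mask(np.zeros((64, 64), dtype=np.uint8))


class TestExtractTiles:
    def test_all_background_yields_no_tiles(self):
        image = np.full((1024, 1024, 3), 245, dtype=np.uint8)
        assert extract_tiles(image, compute_tissue_mask(image)) == []

    def test_fully_covered_slide_yields_full_grid(self):
        slide = full_covered_slide()
        # Otsu needs both classes; hand a fully-on mask to isolate the grid logic
        mask = compute_tissue_mask(slide.image)
        mask.mask[:] = 1
        tiles = extract_tiles(slide.image, mask, tile_size=256)
        # brute-force enumeration of the non-overlapping grid
        expected = {(x, y) for y in range(0, 1024, 256) for x in range(0, 1024, 256)}
        assert {(t.x, t.y) for t in tiles} == expected
        assert len(tiles) == 16

    def test_below_threshold_tile_excluded(self):
        # footprint is 24% tissue at a 25% threshold -> excluded
        image = np.full((256, 256, 3), 245, dtype=np.uint8)
        mask = compute_tissue_mask(image, downsample=32)
        mask.mask[:, :]= 0
        n_on = int(round(0.24 * mask.mask.size))
        mask.mask.flat[:n_on] = 1
        assert extract_tiles(image, mask, tissue_threshold=0.25) == []
        assert len(extract_tiles(image, mask, tissue_threshold=0.23)) == 1

    def test_partial_edge_tiles_discarded(self):
        slide = full_covered_slide()
        mask = compute_tissue_mask(slide.image)
        mask.mask[:] = 1
        tiles = extract_tiles(slide.image[:960, :1024], mask, tile_size=256)
        assert all(t.y + 256 <= 960 for t in tiles)
        assert len(tiles) == 12

    def test_grid_alignment_and_no_overlap(self, quadrant_slide):
        mask = compute_tissue_mask(quadrant_slide.image)
        tiles = extract_tiles(quadrant_slide.image, mask, slide_id="q")
        assert all(t.x % 256 == 0 and t.y % 256 == 0 for t in tiles)
        assert len({(t.x, t.y) for t in tiles}) == len(tiles)

    def test_raising_threshold_never_increases_count(self, quadrant_slide):
        mask = compute_tissue_mask(quadrant_slide.image)
        counts = [len(extract_tiles(quadrant_slide.image, mask, tissue_threshold=t))
                  for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestFilterArtifacts:
    def test_uniform_gray_tile_flagged_blank(self):
        tile = np.full((256, 256, 3), 128, dtype=np.uint8)
        assert "blank" in qc_flags_for_tile(tile)

    def test_textured_tile_retained(self, texture_tiles):
        tiles, _ = texture_tiles
        assert qc_flags_for_tile(tiles[0]) == frozenset()

    def test_black_fraction_flagged_artifact(self, rng):
        # 40% pure-black pixels at rho_max=0.2 -> artifact (brute-force count)
        tile = rng.integers(100, 255, size=(256, 256, 3)).astype(np.uint8)
        n_black = int(0.4 * 256 * 256)
        flat = tile.reshape(-1, 3)
        flat[:n_black] = 0
        gray_black_frac = (tile.reshape(-1, 3).mean(axis=1) <= 10).mean()
        assert gray_black_frac > 0.2
        assert "artifact" in qc_flags_for_tile(tile, rho_max=0.2)

    def test_filter_returns_partition(self, quadrant_slide):
        mask = compute_tissue_mask(quadrant_slide.image)
        tiles = extract_tiles(quadrant_slide.image, mask, slide_id="q")
        retained, flagged = filter_artifacts(tiles, quadrant_slide.image)
        assert len(retained) + len(flagged) == len(tiles)
        assert all(t.qc_flags == frozenset() for t in retained)
        assert all(t.qc_flags for t in flagged)


class TestTileIO:
    def test_write_read_round_trip(self, tmp_path, quadrant_slide):
        mask = compute_tissue_mask(quadrant_slide.image)
        tiles = extract_tiles(quadrant_slide.image, mask, slide_id="q")
        write_tiles(tiles, quadrant_slide.image, tmp_path)
        records, rasters = read_tiles(tmp_path)
        assert records_to_manifest(records).equals(records_to_manifest(tiles))
        assert rasters.shape == (len(tiles), 256, 256, 3)
        np.testing.assert_array_equal(
            rasters[0], quadrant_slide.image[tiles[0].y : tiles[0].y + 256, tiles[0].x : tiles[0].x + 256])

    def test_manifest_row_count_and_png_shape(self, tmp_path, quadrant_slide):
        mask = compute_tissue_mask(quadrant_slide.image)
        tiles = extract_tiles(quadrant_slide.image, mask, slide_id="q")
        manifest_path = write_tiles(tiles, quadrant_slide.image, tmp_path)
        import pandas as pd
        assert len(pd.read_csv(manifest_path)) == len(tiles)

    def test_name_collision_rejected(self, tmp_path, quadrant_slide):
        rec = TileRecord(slide_id="q", x=256, y=256)
        with pytest.raises(ValueError, match="collision"):
            write_tiles([rec, rec], quadrant_slide.image, tmp_path)

    def test_qc_flags_survive_manifest_round_trip(self):
        rec = TileRecord(slide_id="q", x=0, y=0, qc_flags=frozenset({"blank", "artifact"}))
        back = manifest_to_records(records_to_manifest([rec]))
        assert back[0].qc_flags == {"blank", "artifact"}


def test_retained_set_matches_brute_force_recount(quadrant_slide):
    """Oracle equivalence: exhaustive per-pixel grid recount at the recorded threshold."""
    image = quadrant_slide.image
    mask = compute_tissue_mask(image, downsample=32)
    tiles = extract_tiles(image, mask, tile_size=256, tissue_threshold=0.25, slide_id="q")

    small = block_reduce(image.astype(np.float32), (32, 32, 1), np.mean)
    sat = rgb2hsv(small / 255.0)[:, :, 1]
    oracle_mask = sat > mask.threshold_value
    expected = set()
    for y in range(0, image.shape[0] - 255, 256):
        for x in range(0, image.shape[1] - 255, 256):
            block = oracle_mask[y // 32 : (y + 256) // 32, x // 32 : (x + 256) // 32]
            if block.mean() >= 0.25:
                expected.add((x, y))
    assert {(t.x, t.y) for t in tiles} == expected
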