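"""Tile extraction with a histogram-based tissue mask and QC filtering.

A slide raster is first reduced at a 32x downsample, a binary tissue mask is
computed by Otsu thresholding of the saturation channel (background on a
glass slide is near-white, i.e. unsaturated), and non-overlapping 256x256
tiles are kept when at least 25% of their footprint is tissue — a threshold
low enough to retain sparse tissues such as adipose or mucin. Retained tiles
then pass a QC stage that drops blank tiles (no grayscale variation) and
artifact tiles (large saturated-black fraction, or extreme blur measured by
the variance of the Laplacian).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce

DEFAULT_TILE_SIZE = 256
DEFAULT_DOWNSAMPLE = 32
DEFAULT_TISSUE_THRESHOLD = 0.25

# QC defaults (configurable; see filter_artifacts)
SIGMA_MIN = 5.0     # grayscale std below this (of 255) -> blank
RHO_MAX = 0.2       # saturated-black pixel fraction above this -> artifact
LAMBDA_MIN = 10.0   # variance of Laplacian below this -> artifact (blur)
BLACK_LEVEL = 10    # grayscale value at or below which a pixel counts as black

MANIFEST_COLUMNS = ["tile_id", "slide_id", "x", "y", "width", "height", "tissue_fraction", "qc_flags"]


@dataclass
class TileRecord:
    slide_id: str
    x: int
    y: int
    width: int = DEFAULT_TILE_SIZE
    height: int = DEFAULT_TILE_SIZE
    tissue_fraction: float = 0.0
    qc_flags: frozenset[str] = frozenset()

    @property
    def tile_id(self) -> str:
        return f"{self.slide_id}_{self.x}_{self.y}"


@dataclass
class TissueMask:
    mask: np.ndarray  # binary, 1 = tissue
    downsample: int
    threshold_value: float


def compute_tissue_mask(image: np.ndarray, downsample: int = DEFAULT_DOWNSAMPLE) -> TissueMask:
    """Binary tissue mask at a downsample via Otsu on the saturation channel.

    The image is block-averaged by ``downsample`` (mask dimensions are
    ``ceil(dim / downsample)``; edge blocks average the available pixels),
    converted to HSV, and the saturation channel is thresholded with Otsu's
    histogram method. Pixels above the threshold are tissue. A saturation
    channel with no spread (e.g. a uniform near-white slide) yields an empty
    mask and records the maximum saturation as the threshold.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB raster, got shape {image.shape}")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    h, w = image.shape[:2]
    if h < downsample or w < downsample:
        raise ValueError(f"image {w}x{h} smaller than downsample factor {downsample}")
    small = block_reduce(image.astype(np.float32), (downsample, downsample, 1), np.mean)
    sat = rgb2hsv(small / 255.0)[:, :, 1]
    if sat.max() - sat.min() < 1e-6:
        return TissueMask(mask=np.zeros(sat.shape, dtype=np.uint8), downsample=downsample,
                          threshold_value=float(sat.max()))
    thr = float(threshold_otsu(sat))
    return TissueMask(mask=(sat > thr).astype(np.uint8), downsample=downsample, threshold_value=thr)


def extract_tiles(
    image: np.ndarray,
    mask: TissueMask,
    tile_size: int = DEFAULT_TILE_SIZE,
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
    slide_id: str = "slide",
) -> list[TileRecord]:
    """Grid tiles whose mask footprint is at least ``tissue_threshold`` tissue.

    The per-tile tissue fraction is the mean of the downsampled mask over the
    tile footprint (the mask's resolution, not full resolution). Partial edge
    tiles are discarded so every tile is exactly ``tile_size`` square.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not 0.0 <= tissue_threshold <= 1.0:
        raise ValueError("tissue_threshold must be in [0, 1]")
    h, w = image.shape[:2]
    d = mask.downsample
    records = []
    for y in range(0, h - tile_size + 1, tile_size):
        for x in range(0, w - tile_size + 1, tile_size):
            my0, my1 = y // d, -(-(y + tile_size) // d)
            mx0, mx1 = x // d, -(-(x + tile_size) // d)
            frac = float(mask.mask[my0:my1, mx0:mx1].mean())
            if frac >= tissue_threshold:
                records.append(TileRecord(slide_id=slide_id, x=x, y=y, width=tile_size,
                                          height=tile_size, tissue_fraction=frac))
    return records


def tile_pixels(image: np.ndarray, rec: TileRecord) -> np.ndarray:
    return image[rec.y : rec.y + rec.height, rec.x : rec.x + rec.width]


def qc_flags_for_tile(
    tile: np.ndarray,
    sigma_min: float = SIGMA_MIN,
    rho_max: float = RHO_MAX,
    lambda_min: float = LAMBDA_MIN,
) -> frozenset[str]:
    """QC flags for one tile raster: ``blank`` and/or ``artifact``."""
    gray = rgb2gray(tile) * 255.0
    flags = set()
    if gray.std() < sigma_min:
        flags.add("blank")
    black_frac = float((gray <= BLACK_LEVEL).mean())
    lap_var = float(ndimage.laplace(gray).var())
    if black_frac > rho_max or lap_var < lambda_min:
        flags.add("artifact")
    return frozenset(flags)


def filter_artifacts(
    tiles: list[TileRecord],
    image: np.ndarray,
    sigma_min: float = SIGMA_MIN,
    rho_max: float = RHO_MAX,
    lambda_min: float = LAMBDA_MIN,
) -> tuple[list[TileRecord], list[TileRecord]]:
    """Split tiles into (retained, flagged); flagged records carry qc_flags."""
    retained, flagged = [], []
    for rec in tiles:
        flags = qc_flags_for_tile(tile_pixels(image, rec), sigma_min, rho_max, lambda_min)
        if flags:
            flagged.append(TileRecord(rec.slide_id, rec.x, rec.y, rec.width, rec.height,
                                      rec.tissue_fraction, flags))
        else:
            retained.append(rec)
    return retained, flagged


def records_to_manifest(tiles: list[TileRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tile_id": t.tile_id,
                "slide_id": t.slide_id,
                "x": t.x,
                "y": t.y,
                "width": t.width,
                "height": t.height,
                "tissue_fraction": t.tissue_fraction,
                "qc_flags": ";".join(sorted(t.qc_flags)),
            }
            for t in tiles
        ],
        columns=MANIFEST_COLUMNS,
    )


def manifest_to_records(manifest: pd.DataFrame) -> list[TileRecord]:
    records = []
    for row in manifest.itertuples(index=False):
        flags = frozenset(str(row.qc_flags).split(";")) if isinstance(row.qc_flags, str) and row.qc_flags else frozenset()
        records.append(TileRecord(slide_id=row.slide_id, x=int(row.x), y=int(row.y),
                                  width=int(row.width), height=int(row.height),
                                  tissue_fraction=float(row.tissue_fraction), qc_flags=flags))
    return records


def write_tiles(tiles: list[TileRecord], image: np.ndarray, directory: str | Path) -> Path:
    """One PNG per tile named by tile_id, plus a CSV manifest. Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seen = set()
    for rec in tiles:
        if rec.tile_id in seen:
            raise ValueError(f"tile_id collision: {rec.tile_id}")
        seen.add(rec.tile_id)
        iio.imwrite(directory / f"{rec.tile_id}.png", tile_pixels(image, rec), extension=".png")
    manifest_path = directory / "manifest.csv"
    records_to_manifest(tiles).to_csv(manifest_path, index=False)
    return manifest_path


def read_tiles(directory: str | Path) -> tuple[list[TileRecord], np.ndarray]:
    """Read a tile directory back into records plus an ``(n, h, w, 3)`` array."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", keep_default_na=False)
    records = manifest_to_records(manifest)
    rasters = np.stack([iio.imread(directory / f"{rec.tile_id}.png") for rec in records]) if records else \
        np.empty((0, DEFAULT_TILE_SIZE, DEFAULT_TILE_SIZE, 3), dtype=np.uint8)
    return records, rasters
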