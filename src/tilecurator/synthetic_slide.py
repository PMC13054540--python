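"""Seeded synthetic slides with parametric textures and ground-truth masks.

Real whole-slide images are gigapixel scans that cannot ship with a test
suite, so every downstream stage (tiling, autoencoder, clustering, sampling,
curation) is exercised on procedurally generated slides instead: an RGB
raster whose regions carry visually distinct textures on a near-white
background, plus a pixel-level integer label mask. Four texture families are
provided — thresholded Gaussian blobs, sinusoidal stripes, sparse speckle,
and flat color — chosen to be cheap, seeded, and separable enough for an
autoencoder embedding to tell apart.

Coordinates are 0-based, origin top-left, half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

TEXTURE_FAMILIES = ("blob", "stripe", "speckle", "smooth")

DEFAULT_BACKGROUND = (245, 245, 245)


@dataclass(frozen=True)
class TextureSpec:
    """One parametric texture: a family, a base color, a feature scale and contrast."""

    texture_id: int
    family: str
    base_color: tuple[int, int, int]
    scale: float = 8.0
    contrast: float = 0.4

    def validate(self) -> None:
        if self.texture_id <= 0:
            raise ValueError(f"texture_id must be a positive integer, got {self.texture_id}")
        if self.family not in TEXTURE_FAMILIES:
            raise ValueError(f"unknown texture family {self.family!r}; choose from {TEXTURE_FAMILIES}")
        if self.scale < 1:
            raise ValueError(f"scale must be >= 1, got {self.scale}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        for ch in self.base_color:
            if not 0 <= ch <= 255:
                raise ValueError(f"base_color channels must be in [0, 255], got {self.base_color}")


@dataclass(frozen=True)
class Region:
    """A labeled region: an axis-aligned rectangle or a polygon, in level-0 pixels.

    Rectangles are half-open ``(x0, y0, x1, y1)``; polygons are vertex lists.
    """

    texture_id: int
    rect: tuple[int, int, int, int] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("region must define exactly one of rect or polygon")

    def rasterize(self, width: int, height: int) -> np.ndarray:
        """Boolean mask of the region on a ``height x width`` canvas."""
        mask = np.zeros((height, width), dtype=bool)
        if self.rect is not None:
            x0, y0, x1, y1 = self.rect
            if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
                raise ValueError(f"rect {self.rect} outside slide bounds {width}x{height}")
            mask[y0:y1, x0:x1] = True
        else:
            xs = np.array([p[0] for p in self.polygon], dtype=float)
            ys = np.array([p[1] for p in self.polygon], dtype=float)
            if xs.min() < 0 or ys.min() < 0 or xs.max() > width or ys.max() > height:
                raise ValueError("polygon outside slide bounds")
            rr, cc = _sk_polygon(ys, xs, shape=(height, width))
            mask[rr, cc] = True
        return mask


@dataclass
class SlideSpec:
    width: int
    height: int
    textures: list[TextureSpec]
    regions: list[Region]
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND
    seed: int = 0
    slide_id: str = "synthetic"
    tile_size: int = 256

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.width % self.tile_size or self.height % self.tile_size:
            raise ValueError(
                f"slide dimensions {self.width}x{self.height} must be multiples of tile_size={self.tile_size}"
            )
        ids = [t.texture_id for t in self.textures]
        if len(set(ids)) != len(ids):
            raise ValueError("texture_id values must be unique within a slide spec")
        for t in self.textures:
            t.validate()
        known = set(ids)
        for r in self.regions:
            if r.texture_id not in known:
                raise ValueError(f"region references unknown texture_id {r.texture_id}")

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "background_color": list(self.background_color),
            "seed": self.seed,
            "slide_id": self.slide_id,
            "tile_size": self.tile_size,
            "textures": [
                {
                    "texture_id": t.texture_id,
                    "family": t.family,
                    "base_color": list(t.base_color),
                    "scale": t.scale,
                    "contrast": t.contrast,
                }
                for t in self.textures
            ],
            "regions": [
                {"texture_id": r.texture_id, "rect": list(r.rect)}
                if r.rect is not None
                else {"texture_id": r.texture_id, "polygon": [list(p) for p in r.polygon]}
                for r in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlideSpec":
        return cls(
            width=d["width"],
            height=d["height"],
            background_color=tuple(d.get("background_color", DEFAULT_BACKGROUND)),
            seed=d.get("seed", 0),
            slide_id=d.get("slide_id", "synthetic"),
            tile_size=d.get("tile_size", 256),
            textures=[
                TextureSpec(
                    texture_id=t["texture_id"],
                    family=t["family"],
                    base_color=tuple(t["base_color"]),
                    scale=t["scale"],
                    contrast=t["contrast"],
                )
                for t in d["textures"]
            ],
            regions=[
                Region(texture_id=r["texture_id"], rect=tuple(r["rect"]))
                if "rect" in r
                else Region(
                    texture_id=r["texture_id"],
                    polygon=tuple(tuple(p) for p in r["polygon"]),
                )
                for r in d["regions"]
            ],
        )


@dataclass
class SyntheticSlide:
    image: np.ndarray  # (H, W, 3) uint8
    label_mask: np.ndarray  # (H, W) uint8, 0 = background
    spec: SlideSpec = field(repr=False)


def _texture_field(family: str, shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Scalar modulation field in [-1, 1] for one texture family."""
    h, w = shape
    if family == "smooth":
        return np.zeros(shape, dtype=np.float32)
    if family == "blob":
        noise = rng.standard_normal(shape).astype(np.float32)
        smooth = ndimage.gaussian_filter(noise, sigma=scale)
        # two-tone threshold at the median: sharp blob boundaries
        return np.where(smooth > np.median(smooth), 1.0, -1.0).astype(np.float32)
    if family == "stripe":
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / scale + phase).astype(np.float32)
    if family == "speckle":
        # sparse salt-and-pepper dots of roughly `scale` pixels on a plain field
        coarse_h = max(1, int(np.ceil(h / scale)))
        coarse_w = max(1, int(np.ceil(w / scale)))
        present = rng.random((coarse_h, coarse_w)) < 0.12
        sign = np.where(rng.random((coarse_h, coarse_w)) < 0.5, -1.0, 1.0)
        coarse = (present * sign).astype(np.float32)
        return np.kron(coarse, np.ones((int(np.ceil(scale)),) * 2, dtype=np.float32))[:h, :w]
    raise ValueError(f"unknown texture family {family!r}")


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Render a slide spec into an RGB raster and its label mask.

    Deterministic for a fixed spec (texture fields are seeded from
    ``spec.seed`` and the texture id). Overlapping regions are rejected
    because they would make the pixel labels ambiguous.
    """
    spec.validate()
    h, w = spec.height, spec.width
    label = np.zeros((h, w), dtype=np.uint8)
    covered = np.zeros((h, w), dtype=bool)
    image = np.empty((h, w, 3), dtype=np.float32)
    image[...] = np.asarray(spec.background_color, dtype=np.float32)

    fields: dict[int, np.ndarray] = {}
    tex_by_id = {t.texture_id: t for t in spec.textures}
    for region in spec.regions:
        rmask = region.rasterize(w, h)
        clash = covered & rmask
        if clash.any():
            ys, xs = np.nonzero(clash)
            raise ValueError(
                f"overlapping regions: texture {region.texture_id} overlaps an earlier region "
                f"at {clash.sum()} pixels (first at x={xs[0]}, y={ys[0]}); labels would be ambiguous"
            )
        covered |= rmask
        tex = tex_by_id[region.texture_id]
        if region.texture_id not in fields:
            rng = np.random.default_rng((spec.seed, region.texture_id))
            fields[region.texture_id] = _texture_field(tex.family, (h, w), tex.scale, rng)
        f = fields[region.texture_id]
        base = np.asarray(tex.base_color, dtype=np.float32)
        modulated = base[None, :] + 127.5 * tex.contrast * f[rmask, None]
        image[rmask] = modulated
        label[rmask] = region.texture_id

    image = np.clip(image, 0, 255).astype(np.uint8)
    return SyntheticSlide(image=image, label_mask=label, spec=spec)


def write_slide(slide: SyntheticSlide, directory: str | Path) -> dict[str, Path]:
    """Write ``image.tiff``, ``mask.png`` and ``spec.json`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / "image.tiff",
        "mask": directory / "mask.png",
        "spec": directory / "spec.json",
    }
    tifffile.imwrite(paths["image"], slide.image)
    iio.imwrite(paths["mask"], slide.label_mask, extension=".png")
    paths["spec"].write_text(json.dumps(slide.spec.to_dict(), indent=2))
    return paths


def read_slide(directory: str | Path) -> SyntheticSlide:
    directory = Path(directory)
    image = tifffile.imread(directory / "image.tiff")
    mask = iio.imread(directory / "mask.png")
    spec = SlideSpec.from_dict(json.loads((directory / "spec.json").read_text()))
    return SyntheticSlide(image=image, label_mask=np.asarray(mask, dtype=np.uint8), spec=spec)


def tile_ground_truth(slide: SyntheticSlide, tile_size: int = 256, purity_threshold: float = 0.0) -> pd.DataFrame:
    """Majority ground-truth label and purity for every grid tile.

    Returns a DataFrame with columns ``x, y, majority_label, purity`` where
    purity is the fraction of the tile's pixels carrying the majority label.
    Ties break toward the smaller label id. Rows with purity below
    ``purity_threshold`` are dropped (default keeps everything).
    """
    h, w = slide.label_mask.shape
    if h % tile_size or w % tile_size:
        raise ValueError(f"tile_size {tile_size} must divide slide dimensions {w}x{h}")
    rows = []
    n_pix = tile_size * tile_size
    for y in range(0, h, tile_size):
        for x in range(0, w, tile_size):
            block = slide.label_mask[y : y + tile_size, x : x + tile_size]
            counts = np.bincount(block.ravel())
            maj = int(np.argmax(counts))  # argmax takes the smallest index on ties
            purity = counts[maj] / n_pix
            if purity >= purity_threshold:
                rows.append((x, y, maj, purity))
    return pd.DataFrame(rows, columns=["x", "y", "majority_label", "purity"])


def default_texture_palette() -> list[TextureSpec]:
    """Four visually distinct textures with saturated, stain-like base colors."""
    return [
        TextureSpec(1, "blob", (160, 60, 150), scale=12.0, contrast=0.45),   # purple, nuclei-like blobs
        TextureSpec(2, "stripe", (220, 120, 160), scale=14.0, contrast=0.40),  # pink fiber stripes
        TextureSpec(3, "speckle", (120, 40, 60), scale=6.0, contrast=0.55),  # dark red speckle
        TextureSpec(4, "blob", (230, 170, 120), scale=24.0, contrast=0.35),  # pale orange coarse blobs
    ]


def quadrant_slide_spec(
    side: int = 2560,
    region_side: int = 1024,
    margin: int = 256,
    seed: int = 0,
    slide_id: str = "quadrants",
) -> SlideSpec:
    """A slide with four texture regions arranged 2x2 on a white background.

    Regions are aligned to the 256-pixel tile grid so every covered tile is
    pure, which makes the slide a clean fixture for clustering-purity and
    label-propagation checks.
    """
    textures = default_texture_palette()
    step = region_side + margin
    coords = [(margin, margin), (margin + step, margin), (margin, margin + step), (margin + step, margin + step)]
    regions = [
        Region(texture_id=t.texture_id, rect=(x, y, x + region_side, y + region_side))
        for t, (x, y) in zip(textures, coords)
    ]
    return SlideSpec(width=side, height=side, textures=textures, regions=regions, seed=seed, slide_id=slide_id)


def generate_texture_tiles(n: int, seed: int = 0, tile_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """``n`` single-texture tiles cycling through the default palette.

    Returns ``(tiles, labels)``: tiles as ``(n, tile_size, tile_size, 3)``
    uint8, labels as the texture ids. Each tile gets its own seeded texture
    field, so tiles of the same family still vary — a cheap stand-in for the
    morphologic variability of real training tiles.
    """
    palette = default_texture_palette()
    tiles = np.empty((n, tile_size, tile_size, 3), dtype=np.uint8)
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        tex = palette[i % len(palette)]
        rng = np.random.default_rng((seed, i))
        f = _texture_field(tex.family, (tile_size, tile_size), tex.scale, rng)
        base = np.asarray(tex.base_color, dtype=np.float32)
        img = base[None, None, :] + 127.5 * tex.contrast * f[:, :, None]
        tiles[i] = np.clip(img, 0, 255).astype(np.uint8)
        labels[i] = tex.texture_id
    return tiles, labels
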