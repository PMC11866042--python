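"""Tissue masking, grid tile extraction and the analysability filter.

Tiles are 512 x 512 px by default (~113 um square at 0.22 microns per
pixel), cut on a non-overlapping grid anchored at the image origin; edge
tiles that do not fit entirely inside the image are discarded.  A tile is
*analysable* — i.e. usable intertrabecular marrow — when its fat fraction is
strictly below 50% and its bone fraction strictly below 1%.

Tile tables are plain pandas DataFrames with columns
``index, x0, y0, tile_size, tissue_frac, fat_frac, bone_frac, analysable``
(0-based half-open pixel coordinates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color
from skimage.morphology import disk

__all__ = [
    "TILE_COLUMNS",
    "FAT_FRACTION_MAX",
    "BONE_FRACTION_MAX",
    "compute_tissue_mask",
    "extract_tiles",
    "filter_analysable",
    "read_tile_table",
    "write_tile_table",
]

TILE_COLUMNS = [
    "index", "x0", "y0", "tile_size",
    "tissue_frac", "fat_frac", "bone_frac", "analysable",
]

# strict upper bounds on tile composition for analysable marrow
FAT_FRACTION_MAX = 0.50
BONE_FRACTION_MAX = 0.01


def compute_tissue_mask(
    image: np.ndarray,
    luminance_max: float = 0.92,
    saturation_min: float = 0.08,
    closing_radius: int = 5,
    min_object_px: int = 256,
) -> np.ndarray:
    """Classical foreground segmentation of a stained slide image.

    A pixel is tissue when it is either dark (luminance below
    ``luminance_max``) or saturated (HSV saturation above ``saturation_min``);
    the raw mask is then morphologically closed, hole-filled and cleaned of
    small specks.  This stands behind the same interface a learned
    tissue-mask model would occupy.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("compute_tissue_mask: empty image")
    rgb = img.astype(np.float32) / 255.0
    lum = rgb @ np.array([0.2126, 0.7152, 0.0722], dtype=np.float32)
    sat = color.rgb2hsv(rgb)[..., 1]
    mask = (lum < luminance_max) | (sat > saturation_min)
    if closing_radius > 0:
        r = closing_radius
        padded = np.pad(mask, r, mode="edge")  # no spurious border erosion
        mask = ndi.binary_closing(padded, structure=disk(r))[r:-r, r:-r]
    mask = ndi.binary_fill_holes(mask)
    lab, n = ndi.label(mask)
    if n:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = np.isin(lab, np.flatnonzero(sizes >= min_object_px))
    return mask


def _tile_fractions(mask: np.ndarray | None, x0: int, y0: int, ts: int) -> float:
    if mask is None:
        return 0.0
    return float(mask[y0 : y0 + ts, x0 : x0 + ts].mean())


def extract_tiles(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    bone_mask: np.ndarray | None = None,
    fat_mask: np.ndarray | None = None,
    tile_size: int = 512,
    min_tissue_fraction: float = 0.5,
) -> pd.DataFrame:
    """Cut a fixed grid of tiles and keep those sufficiently inside tissue.

    The grid is anchored at (0, 0) with stride ``tile_size`` (no overlap);
    fractions are exact pixel-count ratios over the tile footprint.  Tile
    indices number the kept tiles in row-major grid order.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    h, w = tissue_mask.shape[:2]
    if image is not None and image.shape[:2] != (h, w):
        raise ValueError("image and tissue_mask shapes disagree")
    if tile_size > min(h, w):
        raise ValueError("tile_size exceeds image dimensions")

    rows = []
    idx = 0
    for y0 in range(0, h - tile_size + 1, tile_size):
        for x0 in range(0, w - tile_size + 1, tile_size):
            tfrac = _tile_fractions(tissue_mask, x0, y0, tile_size)
            if tfrac < min_tissue_fraction:
                continue
            ffrac = _tile_fractions(fat_mask, x0, y0, tile_size)
            bfrac = _tile_fractions(bone_mask, x0, y0, tile_size)
            rows.append(
                {
                    "index": idx,
                    "x0": x0,
                    "y0": y0,
                    "tile_size": tile_size,
                    "tissue_frac": tfrac,
                    "fat_frac": ffrac,
                    "bone_frac": bfrac,
                    "analysable": (ffrac < FAT_FRACTION_MAX) and (bfrac < BONE_FRACTION_MAX),
                }
            )
            idx += 1
    return pd.DataFrame(rows, columns=TILE_COLUMNS)


def filter_analysable(table: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the tiles with fat < 50% and bone < 1% (both strict).

    Idempotent; raises if the composition fractions are missing.
    """
    for col in ("fat_frac", "bone_frac"):
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"filter_analysable: missing {col} values")
    keep = (table["fat_frac"] < FAT_FRACTION_MAX) & (table["bone_frac"] < BONE_FRACTION_MAX)
    out = table.loc[keep].copy()
    out["analysable"] = True
    return out.reset_index(drop=True)


def write_tile_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_tile_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tile table missing columns: {missing}")
    return df
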