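"""Slide-level quality control: stain colour, bone preservation, analysable area.

Three axes on which an H&E slide can be compared with its reticulin
counterpart:

1. *Stain intensity variation* — the dominant tissue colour of each slide,
   compared across a cohort in RGB and in CIELAB (D65/2°), where Euclidean
   distances better approximate perceived colour differences.  Silver
   impregnation is far less reproducible than H&E, so the reticulin arm is
   expected to show the larger colour dispersion.
2. *Bone area preservation* — bone tends to detach during destaining and
   silver staining; bone area in mm² quantifies the loss.
3. *Analysable intertrabecular area* — the number of tiles passing the
   fat/bone composition filter, optionally within annotated intertrabecular
   regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCReport",
    "dominant_colour",
    "rgb_to_cielab",
    "colour_variation",
    "compare_dispersion",
    "bone_area",
    "analysable_tile_count",
    "paired_comparison",
]


def dominant_colour(image: np.ndarray, tissue_mask: np.ndarray) -> np.ndarray:
    """Modal tissue colour after quantisation to a 16-level-per-channel cube.

    Tissue pixels are binned into a 16x16x16 RGB cube; the returned colour is
    the mean 8-bit RGB of the pixels in the most populated bin (ties broken
    by lowest bin id), so a uniformly coloured region returns its exact
    colour.  Deterministic by construction.
    """
    mask = np.asarray(tissue_mask, bool)
    if not mask.any():
        raise ValueError("dominant_colour: empty tissue mask")
    px = np.asarray(image)[mask].reshape(-1, 3).astype(np.int64)
    bins = px // 16
    bin_id = bins[:, 0] * 256 + bins[:, 1] * 16 + bins[:, 2]
    counts = np.bincount(bin_id, minlength=4096)
    modal = int(counts.argmax())  # argmax takes the lowest id on ties
    sel = bin_id == modal
    return np.round(px[sel].mean(axis=0)).astype(np.uint8)


# sRGB -> XYZ (D65/2°), exact column sums give the (0.95047, 1, 1.08883)
# white point so that pure white maps to L*=100, a*=b*=0 identically
_SRGB_TO_XYZ = np.array(
    [
        [0.412456439089692, 0.357576077643909, 0.180437483266399],
        [0.212672851405623, 0.715152155287818, 0.072174993306560],
        [0.019333895582329, 0.119192025881303, 0.950304078536368],
    ]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])


def rgb_to_cielab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to CIELAB (D65 white point, 2° observer).

    Standard pipeline: inverse sRGB transfer -> linear RGB -> XYZ -> the
    piecewise cube-root transfer -> L*a*b*.  Accepts a single triple or an
    (..., 3) array; returns float L*a*b* with L* in [0, 100].
    """
    arr = np.asarray(rgb, dtype=np.float64) / 255.0
    flat = arr.reshape(-1, 3)
    lin = np.where(flat <= 0.04045, flat / 12.92, ((flat + 0.055) / 1.055) ** 2.4)
    xyz = (lin @ _SRGB_TO_XYZ.T) / _D65_WHITE
    d = 6.0 / 29.0
    f = np.where(xyz > d**3, np.cbrt(xyz), xyz / (3 * d * d) + 4.0 / 29.0)
    lab = np.column_stack(
        [116.0 * f[:, 1] - 16.0, 500.0 * (f[:, 0] - f[:, 1]), 200.0 * (f[:, 1] - f[:, 2])]
    )
    return lab.reshape(arr.shape)


def colour_variation(colours: np.ndarray) -> dict:
    """Dispersion of per-slide dominant colours in RGB and CIELAB.

    Returns per-channel variances (ddof=1) and the trace of the covariance
    matrix (total dispersion) in both spaces.  Requires >= 2 slides.
    """
    cols = np.asarray(colours, dtype=np.float64)
    if cols.ndim != 2 or cols.shape[0] < 2:
        raise ValueError("colour_variation requires at least two slides")
    lab = rgb_to_cielab(cols.astype(np.uint8))
    out = {}
    for space, data in (("rgb", cols), ("lab", lab)):
        var = data.var(axis=0, ddof=1)
        var[var < 1e-20] = 0.0  # identical colours: snap summation noise
        out[f"{space}_channel_variance"] = var.tolist()
        out[f"{space}_trace"] = float(var.sum())
    return out


def compare_dispersion(
    colours_a: np.ndarray,
    colours_b: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Bootstrap comparison of colour dispersion between two slide arms.

    The statistic is the trace of the CIELAB covariance matrix per arm.  The
    one-sided bootstrap p-value is the fraction of resamples in which arm A's
    trace does not exceed arm B's; ``significant`` flags p < alpha for the
    hypothesis that arm A is more dispersed.
    """
    a = rgb_to_cielab(np.asarray(colours_a, dtype=np.uint8))
    b = rgb_to_cielab(np.asarray(colours_b, dtype=np.uint8))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("compare_dispersion requires >= 2 slides per arm")

    def trace(x):
        return float(x.var(axis=0, ddof=1).sum())

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        ra = a[rng.integers(0, a.shape[0], a.shape[0])]
        rb = b[rng.integers(0, b.shape[0], b.shape[0])]
        if trace(ra) <= trace(rb):
            hits += 1
    p = (hits + 1) / (n_boot + 1)
    return {
        "trace_a": trace(a),
        "trace_b": trace(b),
        "ratio": trace(a) / max(trace(b), 1e-12),
        "p_value": p,
        "significant": p < alpha,
    }


def bone_area(bone_mask: np.ndarray, mpp: float) -> float:
    """Bone area in mm²: pixel count x (mpp / 1000)²."""
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    return float(np.asarray(bone_mask, bool).sum() * (mpp / 1000.0) ** 2)


def analysable_tile_count(table: pd.DataFrame, annotation_mask: np.ndarray | None = None) -> int:
    """Count analysable tiles, optionally restricted to tiles whose centre
    falls inside an annotated (e.g. intact intertrabecular) region."""
    tab = table.loc[table["analysable"].astype(bool)]
    if annotation_mask is None:
        return int(len(tab))
    mask = np.asarray(annotation_mask, bool)
    h, w = mask.shape
    n = 0
    for x0, y0, ts in zip(tab["x0"], tab["y0"], tab["tile_size"]):
        cx = int(x0 + ts // 2)
        cy = int(y0 + ts // 2)
        if 0 <= cx < w and 0 <= cy < h and mask[cy, cx]:
            n += 1
    return n


def paired_comparison(values_a, values_b) -> dict:
    """Paired two-sided Wilcoxon signed-rank test (exact for small n) on a
    per-slide QC quantity measured in both arms."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_comparison needs equal-length arrays, n >= 2")
    if np.allclose(a, b):
        return {"statistic": float("nan"), "p_value": 1.0,
                "mean_a": float(a.mean()), "mean_b": float(b.mean())}
    res = stats.wilcoxon(a, b)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


@dataclass
class QCReport:
    """Per-slide QC summary with optional cohort-level comparisons."""

    slide_ids: list = field(default_factory=list)
    dominant_rgb: list = field(default_factory=list)
    dominant_lab: list = field(default_factory=list)
    bone_area_mm2: list = field(default_factory=list)
    analysable_tiles: list = field(default_factory=list)
    cohort: dict = field(default_factory=dict)

    def add_slide(self, slide_id, image, tissue_mask, bone_mask, mpp, tile_table) -> None:
        rgb = dominant_colour(image, tissue_mask)
        self.slide_ids.append(slide_id)
        self.dominant_rgb.append(rgb.tolist())
        self.dominant_lab.append(np.round(rgb_to_cielab(rgb), 4).tolist())
        self.bone_area_mm2.append(bone_area(bone_mask, mpp))
        self.analysable_tiles.append(analysable_tile_count(tile_table))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": self.slide_ids,
                "dominant_rgb": self.dominant_rgb,
                "dominant_lab": self.dominant_lab,
                "bone_area_mm2": self.bone_area_mm2,
                "analysable_tiles": self.analysable_tiles,
            }
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)
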