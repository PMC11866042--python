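"""False-colour rendering of CIF maps.

Each analysable tile is painted with the colormap colour of its score on the
fixed [0, 1] scale; regions without a scored tile are left unshaded (the
original image shows through).  An optional legend strip with the colour
scale is appended to the right of the canvas so the tile raster itself stays
untouched.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .model import CIFMap

__all__ = ["render_heatmap", "DEFAULT_CMAP"]

DEFAULT_CMAP = "viridis"


def render_heatmap(
    cif_map: CIFMap,
    image: np.ndarray,
    cmap: str = DEFAULT_CMAP,
    legend: bool = True,
    legend_width: int = 40,
) -> np.ndarray:
    """Paint per-tile CIF colours over ``image``; returns an RGB uint8 array.

    Raises when the map's grid geometry does not match the image.
    """
    img = np.asarray(image)
    if img.shape[:2] != tuple(cif_map.image_shape):
        raise ValueError(
            f"geometry mismatch: map is for {cif_map.image_shape}, image is {img.shape[:2]}"
        )
    out = img.copy() if img.ndim == 3 else np.stack([img] * 3, axis=-1)
    cm = colormaps[cmap]
    h, w = out.shape[:2]
    for x0, y0, ts, cif in zip(
        cif_map.scores["x0"], cif_map.scores["y0"],
        cif_map.scores["tile_size"], cif_map.scores["cif"],
    ):
        x0, y0, ts = int(x0), int(y0), int(ts)
        if x0 < 0 or y0 < 0 or x0 + ts > w or y0 + ts > h:
            raise ValueError(f"tile at ({x0}, {y0}) falls outside the image")
        colour = (np.array(cm(float(cif))[:3]) * 255).round().astype(np.uint8)
        out[y0 : y0 + ts, x0 : x0 + ts] = colour
    if legend:
        strip = np.empty((h, legend_width, 3), dtype=np.uint8)
        ramp = np.linspace(1.0, 0.0, h)  # CIF 1 at top
        cols = (np.array([cm(v)[:3] for v in ramp]) * 255).round().astype(np.uint8)
        strip[:] = cols[:, None, :]
        strip[:, :4] = 255  # white gutter
        out = np.concatenate([out, strip], axis=1)
    return out
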