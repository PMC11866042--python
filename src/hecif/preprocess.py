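"""Channel-wise histogram equalisation for stain-variation robustness.

Non-uniform staining shifts and stretches the intensity histogram of each
colour channel differently from slide to slide.  Equalising every channel
against its own cumulative distribution removes global additive shifts
entirely (an unclipped shift leaves the remap output unchanged) while
preserving the within-channel rank order of pixel values, which is what the
downstream ranking model consumes.

The plain global form is used (not CLAHE); statistics are computed per tile
by default, or once per slide via :func:`equalize_channels_joint`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["equalize_channels", "equalize_channels_joint", "channel_lut"]


def channel_lut(channel: np.ndarray) -> np.ndarray:
    """256-entry look-up table equalising one uint8 channel.

    ``v -> round(255 * (cdf(v) - cdf_min) / (n - cdf_min))`` where ``cdf_min``
    is the CDF at the smallest occupied level.  A constant channel maps to
    mid-scale 128 by convention.
    """
    hist = np.bincount(channel.ravel(), minlength=256).astype(np.int64)
    cdf = np.cumsum(hist)
    n = cdf[-1]
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        lut = np.zeros(256, dtype=np.uint8)
        lut[occupied[0]] = 128
        return lut
    cdf_min = cdf[occupied[0]]
    lut = np.round(255.0 * (cdf - cdf_min) / (n - cdf_min))
    return np.clip(lut, 0, 255).astype(np.uint8)


def equalize_channels(image: np.ndarray) -> np.ndarray:
    """Equalise each channel of an 8-bit RGB image independently."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("equalize_channels expects an 8-bit image")
    if img.ndim == 2:
        return channel_lut(img)[img]
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = channel_lut(img[..., c])[img[..., c]]
    return out


def equalize_channels_joint(images: list[np.ndarray]) -> list[np.ndarray]:
    """Equalise a set of tiles with per-slide statistics: one LUT per channel
    computed over all tiles jointly, applied to every tile."""
    if not images:
        return []
    stack = np.stack([np.asarray(im) for im in images])
    if stack.dtype != np.uint8:
        raise ValueError("equalize_channels_joint expects 8-bit images")
    luts = [channel_lut(stack[..., c]) for c in range(stack.shape[-1])]
    return [
        np.stack([luts[c][im[..., c]] for c in range(im.shape[2])], axis=-1)
        for im in stack
    ]
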