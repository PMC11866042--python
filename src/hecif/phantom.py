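"""Synthetic paired-stain bone-marrow phantom generator.

Real inputs to the pipeline are co-sectioned reticulin and H&E whole-slide
images; neither such images nor a teacher model trained on them can ship
with the package, so every downstream stage is exercised on phantoms with a
known ground truth instead.  A phantom carries:

* a latent fibrosis-severity field in [0, 1] (constant or a smoothed random
  field with a stated correlation length),
* tissue, bone-trabecula and fat-vacuole compartments with exactly
  computable area fractions,
* curvilinear fibre strokes rendered in both pseudo-stains, with local
  stroke density a monotone non-decreasing function of the latent field,
* a known affine misalignment between the two stain frames,
* per-slide global stain-colour drift, and an optional bone-loss artefact
  in the pseudo-reticulin rendering (silver impregnation protocols tend to
  detach bone; the QC module measures exactly this).

Strokes are accepted by latent-field thinning from a seed-deterministic
candidate pool, so two phantoms differing only in severity share candidate
geometry and the lower-severity stroke set is a subset of the higher one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform as _SkAffine, warp

from .register import AffineTransform

__all__ = [
    "FibrosisField",
    "Misalignment",
    "PhantomSpec",
    "PhantomPair",
    "generate_phantom",
    "ground_truth_tile_labels",
]

# stain palette (8-bit RGB); chosen to be plausible, not histologically exact
_HE_BACKGROUND = (246, 246, 248)
_HE_TISSUE = (226, 192, 210)
_HE_FAT = (250, 248, 250)
_HE_BONE = (238, 205, 203)
_HE_BONE_RIM = (204, 150, 158)
_HE_STROKE = (168, 78, 118)
_RET_BACKGROUND = (240, 238, 234)
_RET_TISSUE = (208, 202, 192)
_RET_FAT = (247, 246, 243)
_RET_BONE = (231, 206, 202)
_RET_BONE_RIM = (196, 160, 152)
_RET_STROKE = (52, 44, 40)


@dataclass(frozen=True)
class FibrosisField:
    """Latent severity field description.

    ``kind='constant'`` uses ``value`` everywhere.  ``kind='smooth'`` draws
    white noise, Gaussian-smooths it with ``correlation_length_px``, rescales
    to zero mean / unit sd, and maps to ``mean + amplitude * z`` clipped to
    [0, 1].
    """

    kind: str = "constant"
    value: float = 0.5
    mean: float = 0.5
    amplitude: float = 0.35
    correlation_length_px: int = 200

    def realise(self, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            if not 0.0 <= self.value <= 1.0:
                raise ValueError("constant fibrosis value must lie in [0, 1]")
            return np.full(shape, float(self.value), dtype=np.float32)
        if self.kind != "smooth":
            raise ValueError(f"unknown fibrosis field kind {self.kind!r}")
        z = rng.standard_normal(shape)
        z = ndi.gaussian_filter(z, self.correlation_length_px)
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
        return np.clip(self.mean + self.amplitude * z, 0.0, 1.0).astype(np.float32)


@dataclass(frozen=True)
class Misalignment:
    """Affine misalignment of the reticulin frame relative to H&E: rotation
    and isotropic scale about the canvas centre, then a pixel translation."""

    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    width_px: int = 2048
    height_px: int = 2048
    mpp: float = 0.22  # 512-px tile spans ~113 um at this scale
    fibrosis_field: FibrosisField = field(default_factory=FibrosisField)
    n_bone_blobs: int = 3
    fat_fraction: float = 0.08
    misalignment: Misalignment = field(default_factory=Misalignment)
    stain_drift_sd: float = 0.0
    ret_stain_drift_sd: float | None = None  # defaults to stain_drift_sd
    bone_loss_fraction: float = 0.0
    stroke_density_per_mpx: float = 3000.0
    stroke_len_px: int = 36
    tissue_scale: float = 1.0  # multiplies the tissue-blob semi-axes
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if not 0.0 <= self.fat_fraction < 1.0:
            raise ValueError("fat_fraction must lie in [0, 1)")
        if not 0.0 <= self.bone_loss_fraction <= 1.0:
            raise ValueError("bone_loss_fraction must lie in [0, 1]")
        if self.n_bone_blobs < 0:
            raise ValueError("n_bone_blobs must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PhantomPair:
    """A rendered phantom: both stain images, the latent field and masks in
    the H&E frame, reticulin-frame masks, and the true misalignment."""

    reticulin_image: np.ndarray
    he_image: np.ndarray
    fibrosis_field: np.ndarray
    tissue_mask: np.ndarray
    bone_mask: np.ndarray
    fat_mask: np.ndarray
    ret_tissue_mask: np.ndarray
    ret_bone_mask: np.ndarray
    ret_fat_mask: np.ndarray
    ret_fibrosis_field: np.ndarray
    true_affine: AffineTransform
    spec: PhantomSpec

    def save(self, out_dir: str | Path) -> None:
        """Write images (PNG), masks (PNG), field (32-bit TIFF) and the
        spec + true affine as a JSON sidecar."""
        import imageio.v3 as iio
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / "he.png", self.he_image)
        iio.imwrite(out / "reticulin.png", self.reticulin_image)
        for name in ("tissue_mask", "bone_mask", "fat_mask"):
            iio.imwrite(out / f"{name}.png", getattr(self, name).astype(np.uint8) * 255)
        iio.imwrite(out / "ret_tissue_mask.png", self.ret_tissue_mask.astype(np.uint8) * 255)
        iio.imwrite(out / "ret_bone_mask.png", self.ret_bone_mask.astype(np.uint8) * 255)
        tifffile.imwrite(out / "fibrosis_field.tif", self.fibrosis_field.astype(np.float32))
        (out / "phantom.json").write_text(
            self.true_affine.to_json(spec=json.loads(self.spec.to_json()))
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _tissue_blob(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Elongated, slightly lumpy tissue blob with a notch cut from one end.

    The notch breaks the 180-degree symmetry of the principal axis so that
    moment-based registration has a well-defined orientation to recover.
    """
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    cx, cy = w / 2.0, h / 2.0
    base_angle = np.deg2rad(18.0)
    ca, sa = np.cos(base_angle), np.sin(base_angle)
    ts = spec.tissue_scale
    u = ((xx - cx) * ca + (yy - cy) * sa) / (0.34 * w * ts)
    v = (-(xx - cx) * sa + (yy - cy) * ca) / (0.22 * h * ts)
    # low-frequency radial perturbation for a non-ellipse outline
    theta = np.arctan2(v, u)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = rng.uniform(0.02, 0.06, size=3)
    r_mod = 1.0 + sum(a * np.sin((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    blob = (u**2 + v**2) <= r_mod**2
    # notch: remove a disc at one end of the major axis
    nx, ny = cx + 0.30 * w * ts * ca, cy + 0.30 * w * ts * sa
    notch = (xx - nx) ** 2 + (yy - ny) ** 2 <= (0.07 * w * ts) ** 2
    return blob & ~notch


def _stamp_ellipses(
    canvas: np.ndarray,
    allowed: np.ndarray,
    rng: np.random.Generator,
    n: int,
    ax_range: tuple[float, float],
    target_area: float | None = None,
    max_tries: int = 400,
) -> np.ndarray:
    """Stamp random rotated ellipses inside ``allowed`` onto ``canvas``.

    Stops after ``n`` stamps, or earlier/later if ``target_area`` (pixel
    count) is given.  Returns the updated canvas.
    """
    h, w = canvas.shape
    ys, xs = np.nonzero(allowed)
    if xs.size == 0:
        return canvas
    tries = 0
    stamped = 0
    area = int(canvas.sum())
    while tries < max_tries:
        tries += 1
        if target_area is not None and area >= target_area:
            break
        if target_area is None and stamped >= n:
            break
        k = rng.integers(0, xs.size)
        cx, cy = float(xs[k]), float(ys[k])
        a = rng.uniform(*ax_range)
        b = rng.uniform(*ax_range)
        th = rng.uniform(0, np.pi)
        r = int(np.ceil(max(a, b))) + 1
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
        ct, st = np.cos(th), np.sin(th)
        u = ((xx - cx) * ct + (yy - cy) * st) / a
        v = (-(xx - cx) * st + (yy - cy) * ct) / b
        ell = (u**2 + v**2) <= 1.0
        ell &= allowed[y0:y1, x0:x1]
        new = ell & ~canvas[y0:y1, x0:x1]
        area += int(new.sum())
        canvas[y0:y1, x0:x1] |= ell
        stamped += 1
    return canvas


def _make_strokes(
    shape: tuple[int, int],
    sample_region: np.ndarray,
    fibrosis_field: np.ndarray,
    rng: np.random.Generator,
    density_per_mpx: float,
    stroke_len: int,
) -> np.ndarray:
    """Rasterise curvilinear fibre strokes; returns a boolean stroke mask.

    A candidate pool of random-walk strokes is generated independently of the
    field; candidate k survives iff u_k < field(start_k) with u_k ~ U[0, 1).
    Pointwise-larger fields therefore keep supersets of strokes (monotone
    texture density by construction).
    """
    h, w = shape
    area = int(sample_region.sum())
    if area == 0:
        return np.zeros(shape, dtype=bool)
    n_cand = int(round(density_per_mpx * area / 1e6))
    if n_cand == 0:
        return np.zeros(shape, dtype=bool)

    ys, xs = np.nonzero(sample_region)
    pick = rng.integers(0, xs.size, size=n_cand)
    x0 = xs[pick].astype(np.float32) + rng.uniform(-0.5, 0.5, n_cand).astype(np.float32)
    y0 = ys[pick].astype(np.float32) + rng.uniform(-0.5, 0.5, n_cand).astype(np.float32)
    u = rng.uniform(0.0, 1.0, size=n_cand)
    head = rng.uniform(0, 2 * np.pi, size=n_cand).astype(np.float32)
    turns = rng.normal(0.0, 0.35, size=(n_cand, stroke_len - 1)).astype(np.float32)

    keep = u < fibrosis_field[ys[pick], xs[pick]]
    if not keep.any():
        return np.zeros(shape, dtype=bool)

    ang = np.cumsum(np.concatenate([head[keep, None], turns[keep]], axis=1), axis=1)
    step = 1.2
    px = np.cumsum(np.cos(ang) * step, axis=1) + x0[keep, None]
    py = np.cumsum(np.sin(ang) * step, axis=1) + y0[keep, None]
    ix = np.clip(np.round(px).astype(np.int64), 0, w - 1)
    iy = np.clip(np.round(py).astype(np.int64), 0, h - 1)
    mask = np.zeros(shape, dtype=bool)
    mask[iy.ravel(), ix.ravel()] = True
    mask &= sample_region
    return mask


def _paint(
    shape: tuple[int, int],
    background: tuple,
    layers: list[tuple[np.ndarray, tuple]],
) -> np.ndarray:
    img = np.empty((*shape, 3), dtype=np.float32)
    img[:] = background
    for mask, colour in layers:
        img[mask] = colour
    return img


def _rim(mask: np.ndarray, width: int = 4) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask, iterations=width)


def _warp_to_ret(arr: np.ndarray, affine: AffineTransform, order: int) -> np.ndarray:
    """Sample an H&E-frame raster in the reticulin frame: ret(x) = he(A x)."""
    tf = _SkAffine(matrix=affine.as_3x3())
    out = warp(arr.astype(np.float32), inverse_map=tf, order=order, mode="constant", cval=0.0)
    return out


def _erode_to_fraction(mask: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Erode a mask from its boundary until ~keep_fraction of its area remains."""
    if keep_fraction >= 1.0 or not mask.any():
        return mask
    if keep_fraction <= 0.0:
        return np.zeros_like(mask)
    dt = ndi.distance_transform_edt(mask)
    target = int(round(mask.sum() * keep_fraction))
    # keep exactly `target` deepest pixels; ties broken by flat index so the
    # kept area matches the requested fraction to one pixel
    flat = np.flatnonzero(mask)
    order = np.argsort(-dt.ravel()[flat], kind="stable")
    out = np.zeros(mask.size, dtype=bool)
    out[flat[order[:target]]] = True
    return out.reshape(mask.shape)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render a deterministic paired-stain phantom from ``spec``.

    The H&E scene (masks, field, texture) is built in the H&E frame; the
    reticulin frame is related to it by exactly ``spec.misalignment`` (as
    ``true_affine``: reticulin coords -> H&E coords), with fresh stroke
    instances drawn in the reticulin frame and the bone compartment eroded by
    ``bone_loss_fraction`` to emulate silver-stain bone detachment.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)

    tissue = _tissue_blob(spec, rng)
    fibrosis = spec.fibrosis_field.realise(shape, rng)

    # bone trabeculae near the tissue boundary, then fat avoiding bone
    bone = np.zeros(shape, dtype=bool)
    depth = ndi.distance_transform_edt(tissue)
    interior = depth > 10
    band = (depth > 10) & (depth < 0.08 * min(h, w))
    scale = min(h, w) / 2048.0
    bone = _stamp_ellipses(
        bone, band, rng, n=spec.n_bone_blobs,
        ax_range=(45 * scale + 6, 110 * scale + 10),
    )
    bone &= tissue
    fat = np.zeros(shape, dtype=bool)
    if spec.fat_fraction > 0:
        fat = _stamp_ellipses(
            fat, interior & ~ndi.binary_dilation(bone, iterations=3), rng,
            n=10_000, ax_range=(6 * scale + 3, 16 * scale + 4),
            target_area=spec.fat_fraction * tissue.sum(),
        )
    fat &= ~bone

    # the true misalignment, reticulin frame -> H&E frame
    mis = spec.misalignment
    true_affine = AffineTransform.from_params(
        rotation_deg=mis.rotation_deg,
        translation=tuple(mis.translation_px),
        scale=mis.scale,
        center=(w / 2.0, h / 2.0),
    )

    ret_tissue = _warp_to_ret(tissue, true_affine, order=0) > 0.5
    if not ret_tissue.any():
        raise ValueError("misalignment maps all tissue outside the reticulin canvas")
    ret_bone_full = _warp_to_ret(bone, true_affine, order=0) > 0.5
    ret_fat = _warp_to_ret(fat, true_affine, order=0) > 0.5
    ret_fib = _warp_to_ret(fibrosis, true_affine, order=1).astype(np.float32)
    ret_bone = _erode_to_fraction(ret_bone_full, 1.0 - spec.bone_loss_fraction)
    ret_fat &= ~ret_bone

    # fibre strokes: intertrabecular tissue only, density ~ latent severity
    marrow_he = tissue & ~bone & ~fat
    strokes_he = _make_strokes(
        shape, marrow_he, fibrosis, rng, spec.stroke_density_per_mpx, spec.stroke_len_px
    )
    strokes_he = ndi.binary_dilation(strokes_he) & marrow_he
    marrow_ret = ret_tissue & ~ret_bone & ~ret_fat
    strokes_ret = _make_strokes(
        shape, marrow_ret, ret_fib, rng, spec.stroke_density_per_mpx, spec.stroke_len_px
    )
    strokes_ret = ndi.binary_dilation(strokes_ret) & marrow_ret

    he = _paint(
        shape, _HE_BACKGROUND,
        [
            (tissue, _HE_TISSUE),
            (fat, _HE_FAT),
            (bone, _HE_BONE),
            (_rim(bone), _HE_BONE_RIM),
            (strokes_he, _HE_STROKE),
        ],
    )
    ret = _paint(
        shape, _RET_BACKGROUND,
        [
            (ret_tissue, _RET_TISSUE),
            (ret_fat, _RET_FAT),
            (ret_bone, _RET_BONE),
            (_rim(ret_bone), _RET_BONE_RIM),
            (strokes_ret, _RET_STROKE),
        ],
    )

    # per-slide global stain drift, one additive shift per channel
    he_sd = spec.stain_drift_sd
    ret_sd = spec.ret_stain_drift_sd if spec.ret_stain_drift_sd is not None else he_sd
    he += rng.normal(0.0, he_sd, size=3).astype(np.float32) if he_sd > 0 else 0.0
    ret += rng.normal(0.0, ret_sd, size=3).astype(np.float32) if ret_sd > 0 else 0.0

    return PhantomPair(
        reticulin_image=np.clip(ret, 0, 255).astype(np.uint8),
        he_image=np.clip(he, 0, 255).astype(np.uint8),
        fibrosis_field=fibrosis,
        tissue_mask=tissue,
        bone_mask=bone,
        fat_mask=fat,
        ret_tissue_mask=ret_tissue,
        ret_bone_mask=ret_bone,
        ret_fat_mask=ret_fat,
        ret_fibrosis_field=ret_fib,
        true_affine=true_affine,
        spec=spec,
    )


def ground_truth_tile_labels(pair: PhantomPair, tile_table) -> np.ndarray:
    """Per-tile mean of the latent fibrosis field (the phantom 'teacher').

    Labels play the role of per-tile scores that a pretrained reticulin-based
    model would supply for real slides.  Raises if a tile leaves the raster,
    naming the offending tile index.
    """
    field_arr = pair.fibrosis_field
    h, w = field_arr.shape
    labels = np.empty(len(tile_table), dtype=np.float64)
    for pos, (idx, x0, y0, ts) in enumerate(
        zip(tile_table["index"], tile_table["x0"], tile_table["y0"], tile_table["tile_size"])
    ):
        x0, y0, ts = int(x0), int(y0), int(ts)
        if x0 < 0 or y0 < 0 or x0 + ts > w or y0 + ts > h:
            raise ValueError(f"tile {int(idx)} lies outside the fibrosis field raster")
        labels[pos] = float(field_arr[y0 : y0 + ts, x0 : x0 + ts].mean(dtype=np.float64))
    return labels
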