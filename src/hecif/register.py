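"""Affine registration of paired stain slides from their tissue masks.

A reticulin slide and its H&E counterpart come from the same physical
section, so a single global affine transform (rotation + isotropic scale +
translation, small shears absorbed by the linear part) relates their pixel
grids.  The transform is estimated from the two binary tissue masks alone:
moment-based initialisation (centroids, principal axes, area ratio)
followed by local refinement that maximises the overlap of Gaussian-smoothed
masks.  The final quality is reported as the intersection-over-union (IoU)
of the binary masks in the destination frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize

__all__ = [
    "AffineTransform",
    "RegistrationResult",
    "estimate_affine",
    "map_coords",
    "pair_tiles",
    "TilePair",
]


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine map from source (x, y) pixel coordinates to destination.

    ``matrix`` is ``[[a, b, tx], [c, d, ty]]`` acting on column vectors
    ``(x, y, 1)``.  The linear part must be invertible.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) <= 1e-9:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        scale: float = 1.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Rotation+scale about ``center`` followed by ``translation``.

        This is the parameterisation used for phantom misalignments: the
        tissue is rotated/scaled in place about the given pivot (usually the
        canvas centre) and then shifted.
        """
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        lin = scale * np.array([[c, -s], [s, c]])
        cx, cy = center
        cvec = np.array([cx, cy])
        t = np.asarray(translation, dtype=float) + cvec - lin @ cvec
        return cls(np.column_stack([lin, t]))

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        return cls(np.array(json.loads(text)["matrix"]))

    # -- algebra -----------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def as_3x3(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return AffineTransform((self.as_3x3() @ other.as_3x3())[:2])

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.as_3x3())[:2])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def params(self, center: tuple[float, float] = (0.0, 0.0)) -> dict:
        """Decompose into rotation (deg), isotropic scale and translation
        under the :meth:`from_params` convention with the given pivot."""
        lin = self.linear
        scale = float(np.sqrt(abs(np.linalg.det(lin))))
        rot = float(np.rad2deg(np.arctan2(lin[1, 0], lin[0, 0])))
        cvec = np.asarray(center, dtype=float)
        trans = self.translation - cvec + lin @ cvec
        return {"rotation_deg": rot, "scale": scale, "translation": tuple(trans)}

    def to_json(self, **extra) -> str:
        return json.dumps({"matrix": self.matrix.tolist(), **extra}, indent=2)


def map_coords(t: AffineTransform, points) -> np.ndarray:
    """Apply ``t`` to an (n, 2) array of (x, y) points (or a single point)."""
    return t.apply(points)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    transform: AffineTransform
    iou: float
    success: bool
    init_iou: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.transform.matrix.tolist(),
                "iou": self.iou,
                "success": self.success,
                "init_iou": self.init_iou,
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )


def _mask_moments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    ys, xs = np.nonzero(mask)
    n = xs.size
    centroid = np.array([xs.mean(), ys.mean()])
    dx, dy = xs - centroid[0], ys - centroid[1]
    cov = np.array([[dx @ dx, dx @ dy], [dx @ dy, dy @ dy]]) / n
    return centroid, cov, float(n)


def _principal_angle(cov: np.ndarray) -> float:
    return 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])


def _warp_mask(mask: np.ndarray, t: AffineTransform, shape: tuple[int, int]) -> np.ndarray:
    """Warp a source-frame mask into the destination frame under ``t``."""
    # output(yx) = input(inv(t)(yx)); ndi works in (row, col) = (y, x)
    inv = t.inverse().as_3x3()
    m_yx = np.array(
        [
            [inv[1, 1], inv[1, 0], inv[1, 2]],
            [inv[0, 1], inv[0, 0], inv[0, 2]],
        ]
    )
    return ndi.affine_transform(
        mask.astype(np.float32),
        m_yx[:, :2],
        offset=m_yx[:, 2],
        output_shape=shape,
        order=1,
        mode="constant",
        cval=0.0,
    )


def mask_iou(mask_src: np.ndarray, mask_dst: np.ndarray, t: AffineTransform) -> float:
    """IoU of ``t``-warped source mask and destination mask (binary)."""
    w = _warp_mask(np.asarray(mask_src, bool), t, mask_dst.shape) > 0.5
    dst = np.asarray(mask_dst, bool)
    union = np.logical_or(w, dst).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(w, dst).sum() / union)


def _params_to_transform(p: np.ndarray, c_src: np.ndarray, c_dst: np.ndarray) -> AffineTransform:
    """(theta, log_scale, dx, dy): rotate/scale about the source centroid and
    map it onto the destination centroid plus (dx, dy)."""
    th, ls, dx, dy = p
    s = np.exp(ls)
    cth, sth = np.cos(th), np.sin(th)
    lin = s * np.array([[cth, -sth], [sth, cth]])
    t = c_dst + np.array([dx, dy]) - lin @ c_src
    return AffineTransform(np.column_stack([lin, t]))


def estimate_affine(
    mask_src: np.ndarray,
    mask_dst: np.ndarray,
    refine: bool = True,
    iou_floor: float = 0.5,
    max_coarse_px: int = 384,
) -> RegistrationResult:
    """Estimate the affine transform aligning ``mask_src`` onto ``mask_dst``.

    Initialisation: centroid translation, principal-axis rotation (both 180°
    candidates are tried and the higher-IoU one kept) and isotropic scale from
    the area ratio.  Refinement: Powell search over (rotation, log-scale,
    translation) maximising the correlation of Gaussian-smoothed masks on a
    coarse grid, then re-scored at full resolution.

    Raises ``ValueError`` on an empty mask.  A final IoU below ``iou_floor``
    is reported as ``success=False``.
    """
    src = np.asarray(mask_src, bool)
    dst = np.asarray(mask_dst, bool)
    if not src.any() or not dst.any():
        raise ValueError("estimate_affine: empty tissue mask")

    c_src, cov_src, n_src = _mask_moments(src)
    c_dst, cov_dst, n_dst = _mask_moments(dst)
    scale0 = np.sqrt(n_dst / n_src)
    dth0 = _principal_angle(cov_dst) - _principal_angle(cov_src)

    best = None
    for dth in (dth0, dth0 + np.pi):
        t = _params_to_transform(np.array([dth, np.log(scale0), 0.0, 0.0]), c_src, c_dst)
        iou = mask_iou(src, dst, t)
        if best is None or iou > best[1]:
            best = ((dth, np.log(scale0), 0.0, 0.0), iou)
    p0, init_iou = np.array(best[0]), best[1]
    # keep the angle in (-pi, pi] so parameter recovery is unambiguous
    p0[0] = np.arctan2(np.sin(p0[0]), np.cos(p0[0]))

    if refine:
        # coarse, smoothed objective: piecewise-constant IoU is unusable for
        # a local optimiser, blurred-mask correlation is smooth in all 4 dofs
        f = max(1, int(np.ceil(max(src.shape + dst.shape) / max_coarse_px)))
        src_c = ndi.gaussian_filter(src[::f, ::f].astype(np.float32), 2.0)
        dst_c = ndi.gaussian_filter(dst[::f, ::f].astype(np.float32), 2.0)
        cs, cd = c_src / f, c_dst / f

        def neg_overlap(p):
            t = _params_to_transform(
                np.array([p[0], p[1], p[2], p[3]]), cs, cd
            )
            w = _warp_mask(src_c, t, dst_c.shape)
            return -float((w * dst_c).sum())

        res = minimize(
            neg_overlap,
            np.array([p0[0], p0[1], p0[2] / f, p0[3] / f]),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 400},
        )
        p = np.array([res.x[0], res.x[1], res.x[2] * f, res.x[3] * f])
    else:
        p = p0

    transform = _params_to_transform(p, c_src, c_dst)
    iou = mask_iou(src, dst, transform)
    if iou < init_iou:  # refinement must never make things worse
        transform = _params_to_transform(p0, c_src, c_dst)
        iou = init_iou
    return RegistrationResult(
        transform=transform,
        iou=iou,
        success=iou >= iou_floor,
        init_iou=init_iou,
        diagnostics={"refined": bool(refine)},
    )


# ---------------------------------------------------------------------------
# tile pairing
# ---------------------------------------------------------------------------

@dataclass
class TilePair:
    index: int
    src_x0: int
    src_y0: int
    dst_x0: int
    dst_y0: int
    tile_size: int
    dst_tile: np.ndarray | None = None
    src_tile: np.ndarray | None = None
    label: float | None = None


def pair_tiles(
    src_table,
    t: AffineTransform,
    dst_image: np.ndarray,
    src_image: np.ndarray | None = None,
) -> list[TilePair]:
    """Map each source-tile centre through ``t`` and cut the matching
    destination tile (same pixel size, centred on the mapped centre).

    Destination tiles falling partly outside the destination raster are
    dropped; the H&E pixels are extracted unresampled, which preserves the
    native texture for training.  Raises if every tile is clipped.
    """
    h, w = dst_image.shape[:2]
    pairs: list[TilePair] = []
    for idx, x0, y0, ts in zip(
        src_table["index"], src_table["x0"], src_table["y0"], src_table["tile_size"]
    ):
        ts = int(ts)
        centre = np.array([x0 + ts / 2.0, y0 + ts / 2.0])
        mx, my = map_coords(t, centre)
        dx0 = int(round(mx - ts / 2.0))
        dy0 = int(round(my - ts / 2.0))
        if dx0 < 0 or dy0 < 0 or dx0 + ts > w or dy0 + ts > h:
            continue
        pair = TilePair(
            index=int(idx),
            src_x0=int(x0),
            src_y0=int(y0),
            dst_x0=dx0,
            dst_y0=dy0,
            tile_size=ts,
            dst_tile=dst_image[dy0 : dy0 + ts, dx0 : dx0 + ts].copy(),
        )
        if src_image is not None:
            pair.src_tile = src_image[
                pair.src_y0 : pair.src_y0 + ts, pair.src_x0 : pair.src_x0 + ts
            ].copy()
        pairs.append(pair)
    if not pairs:
        raise ValueError("pair_tiles: every mapped tile falls outside the destination image")
    return pairs
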