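"""Ranking-CNN training and continuous fibrosis scoring (CIF).

Fibrosis severity is a continuum, not a 4-point grade.  Instead of
regressing absolute labels, the model is trained on *ordered pairs* of
tiles: whenever the teacher score of tile i exceeds that of tile j by at
least a gap delta, the network's scalar output for i is pushed above that
for j through a pairwise logistic (RankNet-style) or hinge loss.  The
learned scalar is then mapped to the CIF range [0, 1] by min-max
calibration over the training-set outputs (clipped), and per-tile scores
are aggregated to a slide score by the arithmetic mean.

The teacher is any callable producing per-tile labels; on phantoms it is
the latent ground-truth field, standing in for a pretrained reticulin-based
scorer.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.transform import resize

from .nn import Adam, Conv2d, GlobalAvgPool, Linear, MaxPool2, ReLU, Sequential

__all__ = [
    "RankingTrainConfig",
    "CIFMap",
    "make_training_pairs",
    "train_ranking_model",
    "predict_cif",
    "RankingModel",
    "prepare_tiles",
]


@dataclass(frozen=True)
class RankingTrainConfig:
    """Hyper-parameters of the ranking model.

    ``input_px`` is the side length tiles are resized to before entering the
    network (512 native; 64 is the desk-scale default).  ``delta`` is the
    minimum teacher-label gap for a pair to count as ordered.
    """

    channels: tuple[int, ...] = (8, 16, 32)
    input_px: int = 64
    loss: str = "logistic"  # or "hinge"
    margin: float = 1.0
    lr: float = 2e-3
    batch_pairs: int = 16
    epochs: int = 12
    delta: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("logistic", "hinge"):
            raise ValueError(f"unknown loss {self.loss!r}")


def make_training_pairs(
    labels: np.ndarray,
    delta: float,
    seed: int = 0,
    n_pairs: int | None = None,
    exhaustive: bool = False,
) -> np.ndarray:
    """Ordered (higher, lower) index pairs with label gap >= delta.

    Exhaustive mode enumerates every qualifying ordered pair; otherwise
    ``n_pairs`` (default ``4 * len(labels)``) are drawn uniformly with
    replacement from that set, deterministically for a given seed.
    """
    lab = np.asarray(labels, dtype=float)
    if lab.size < 2:
        raise ValueError("need at least two labelled tiles")
    diff = lab[:, None] - lab[None, :]
    hi, lo = np.nonzero(diff >= delta)
    if hi.size == 0:
        raise ValueError(
            f"no tile pair has a label gap >= {delta}; use a smaller delta"
        )
    all_pairs = np.column_stack([hi, lo])
    if exhaustive:
        return all_pairs
    rng = np.random.default_rng(seed)
    n_pairs = n_pairs if n_pairs is not None else 4 * lab.size
    return all_pairs[rng.integers(0, all_pairs.shape[0], size=n_pairs)]


def prepare_tiles(tiles: np.ndarray, input_px: int) -> np.ndarray:
    """uint8 (N, H, W, 3) tiles -> float32 (N, 3, input_px, input_px) in [0, 1]."""
    arr = np.asarray(tiles)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("tiles must be (N, H, W, 3)")
    if arr.shape[1] != input_px:
        arr = np.stack(
            [
                resize(t, (input_px, input_px), order=1, anti_aliasing=True, preserve_range=True)
                for t in arr
            ]
        )
    x = arr.astype(np.float32)
    if x.max() > 1.5:
        x /= 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _build_network(config: RankingTrainConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    c_in = 3
    for c_out in config.channels:
        layers += [Conv2d(c_in, c_out, rng=rng), ReLU(), MaxPool2()]
        c_in = c_out
    layers += [GlobalAvgPool(), Linear(c_in, 1, rng=rng)]
    return Sequential(layers)


class RankingModel:
    """A trained ranking network plus its [0, 1] score calibration."""

    def __init__(self, net: Sequential, config: RankingTrainConfig,
                 calibration: tuple[float, float] | None = None,
                 history: list | None = None):
        self.net = net
        self.config = config
        self.calibration = calibration
        self.history = history or []

    def raw_scores(self, tiles: np.ndarray, batch: int = 64) -> np.ndarray:
        x = prepare_tiles(tiles, self.config.input_px)
        out = [self.net.forward(x[i : i + batch])[:, 0] for i in range(0, x.shape[0], batch)]
        return np.concatenate(out) if out else np.empty(0, dtype=np.float32)

    def fit_calibration(self, train_tiles: np.ndarray) -> None:
        raw = self.raw_scores(train_tiles)
        lo, hi = float(raw.min()), float(raw.max())
        if hi - lo < 1e-12:
            hi = lo + 1e-12
        self.calibration = (lo, hi)

    def scores(self, tiles: np.ndarray) -> np.ndarray:
        if self.calibration is None:
            raise ValueError("model is uncalibrated; call fit_calibration first")
        lo, hi = self.calibration
        return np.clip((self.raw_scores(tiles) - lo) / (hi - lo), 0.0, 1.0)

    def history_hash(self) -> int:
        """Checksum of the training curve, for reproducibility checks."""
        return zlib.crc32(np.asarray(self.history, dtype=np.float64).tobytes())

    # -- persistence -------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "calibration": self.calibration,
            "history": self.history,
        }
        state = self.net.state_dict()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "RankingModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = dict(meta["config"])
            cfg_dict["channels"] = tuple(cfg_dict["channels"])
            config = RankingTrainConfig(**cfg_dict)
            net = _build_network(config, np.random.default_rng(config.seed))
            net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        cal = meta["calibration"]
        return cls(net, config, tuple(cal) if cal is not None else None, meta["history"])


def train_ranking_model(
    pairs: np.ndarray,
    tiles: np.ndarray,
    config: RankingTrainConfig,
    log: list | None = None,
) -> RankingModel:
    """Optimise the pairwise ranking loss over ordered tile pairs.

    ``pairs`` holds (higher, lower) indices into ``tiles``.  One epoch visits
    every pair once in a seeded random order, in mini-batches of
    ``batch_pairs``.  The per-epoch mean loss is recorded; a NaN loss aborts
    with the offending configuration in the message.
    """
    pairs = np.asarray(pairs)
    if pairs.ndim != 2 or pairs.shape[0] == 0:
        raise ValueError("pairs must be a non-empty (n, 2) array")
    x = prepare_tiles(tiles, config.input_px)
    rng = np.random.default_rng(config.seed)
    net = _build_network(config, rng)
    opt = Adam(net, lr=config.lr)
    n_pairs = pairs.shape[0]
    bsz = min(config.batch_pairs, n_pairs)
    history: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n_pairs)
        losses = []
        for start in range(0, n_pairs, bsz):
            batch = pairs[order[start : start + bsz]]
            b = batch.shape[0]
            xb = np.concatenate([x[batch[:, 0]], x[batch[:, 1]]])
            s = net.forward(xb)[:, 0]
            d = s[:b] - s[b:]
            if config.loss == "logistic":
                loss = float(np.mean(np.logaddexp(0.0, -d)))
                g = expit(-d) * -1.0  # d/dd of log(1+e^-d), overflow-safe
            else:
                viol = config.margin - d
                loss = float(np.mean(np.maximum(viol, 0.0)))
                g = -(viol > 0).astype(np.float32)
            if not np.isfinite(loss):
                raise RuntimeError(f"ranking loss diverged (NaN/inf); config={asdict(config)}")
            dscores = np.concatenate([g, -g]).astype(np.float32) / b
            net.backward(dscores[:, None])
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if log is not None:
            log.append(history[-1])

    model = RankingModel(net, config, history=history)
    model.fit_calibration(tiles)
    return model


# ---------------------------------------------------------------------------
# CIF maps
# ---------------------------------------------------------------------------

@dataclass
class CIFMap:
    """Per-tile continuous fibrosis scores on a slide grid.

    ``scores`` is a DataFrame with columns index, x0, y0, tile_size, cif;
    ``image_shape`` fixes the grid geometry for rendering.  The slide-level
    aggregate is the arithmetic mean of the listed tiles.
    """

    scores: pd.DataFrame
    image_shape: tuple[int, int]

    def __post_init__(self):
        cif = self.scores["cif"].to_numpy(dtype=float)
        if cif.size and (cif.min() < 0.0 or cif.max() > 1.0):
            raise ValueError("CIF scores must lie in [0, 1]")

    @property
    def aggregate(self) -> float:
        return float(self.scores["cif"].mean())

    @property
    def tile_size(self) -> int:
        return int(self.scores["tile_size"].iloc[0])

    def tile_centres(self) -> np.ndarray:
        ts = self.scores["tile_size"].to_numpy(dtype=float)
        return np.column_stack(
            [self.scores["x0"].to_numpy(dtype=float) + ts / 2.0,
             self.scores["y0"].to_numpy(dtype=float) + ts / 2.0]
        )

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, image_shape) -> "CIFMap":
        return cls(pd.read_csv(path), tuple(image_shape))


def predict_cif(
    model: RankingModel,
    tiles: np.ndarray,
    tile_table: pd.DataFrame,
    image_shape: tuple[int, int],
) -> CIFMap:
    """Score tiles with a calibrated model and assemble a :class:`CIFMap`.

    ``tile_table`` rows must align one-to-one with ``tiles``.
    """
    if len(tile_table) != len(tiles):
        raise ValueError("tile_table and tiles length mismatch")
    cif = model.scores(tiles)
    df = pd.DataFrame(
        {
            "index": np.asarray(tile_table["index"], dtype=int),
            "x0": np.asarray(tile_table["x0"], dtype=int),
            "y0": np.asarray(tile_table["y0"], dtype=int),
            "tile_size": np.asarray(tile_table["tile_size"], dtype=int),
            "cif": np.round(cif.astype(np.float64), 6),
        }
    )
    return CIFMap(scores=df, image_shape=tuple(image_shape))
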