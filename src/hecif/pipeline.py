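"""End-to-end orchestration: simulate/load -> mask -> register -> tile ->
label -> preprocess -> train -> predict -> heatmap -> QC -> subsample.

The pipeline mirrors the paired-stain workflow: tiles are extracted in the
reticulin frame (where the teacher operates), mapped through the estimated
affine transform to cut matched H&E tiles, and the ranking model is trained
on H&E tiles ordered by the teacher's labels.  Scoring, heatmaps, QC and
the subsampling analysis then run on the H&E side.

Every run writes a provenance record (config hash, seeds, package version,
artefact index); reruns with identical inputs reproduce identical score
tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .cifmodel import (
    CIFMap,
    RankingTrainConfig,
    make_training_pairs,
    predict_cif,
    render_heatmap,
    train_ranking_model,
)
from .cifmodel.metrics import pairwise_prediction_accuracy
from .manifest import PairManifest, SampleEntry
from .phantom import (
    FibrosisField,
    Misalignment,
    PhantomPair,
    PhantomSpec,
    generate_phantom,
)
from .preprocess import equalize_channels
from .qc import QCReport, colour_variation, compare_dispersion, paired_comparison
from .register import estimate_affine, pair_tiles
from .subsample import DEFAULT_FRACTIONS, cohort_adequacy_summary, deviation_curve
from .tiling import compute_tissue_mask, extract_tiles

__all__ = [
    "PipelineConfig",
    "run_end_to_end",
    "prepare_samples",
    "train_from_samples",
    "phantom_spec_from_dict",
]


@dataclass(frozen=True)
class PipelineConfig:
    tile_size: int = 128
    min_tissue_fraction: float = 0.5
    apply_composition_filter_for_training: bool = False
    train_fraction: float = 0.75
    train: RankingTrainConfig = field(default_factory=RankingTrainConfig)
    subsample_fractions: tuple = tuple(str(f) for f in DEFAULT_FRACTIONS)
    subsample_draws: int = 20
    heterogeneity_threshold: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subsample_fractions"] = list(self.subsample_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            tr = dict(d["train"])
            if "channels" in tr:
                tr["channels"] = tuple(tr["channels"])
            d["train"] = RankingTrainConfig(**tr)
        if "subsample_fractions" in d:
            d["subsample_fractions"] = tuple(str(f) for f in d["subsample_fractions"])
        return cls(**d)


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if isinstance(d.get("fibrosis_field"), dict):
        d["fibrosis_field"] = FibrosisField(**d["fibrosis_field"])
    if isinstance(d.get("misalignment"), dict):
        mis = dict(d["misalignment"])
        if "translation_px" in mis:
            mis["translation_px"] = tuple(mis["translation_px"])
        d["misalignment"] = Misalignment(**mis)
    return PhantomSpec(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id


@dataclass
class _SampleData:
    entry: SampleEntry
    he_image: np.ndarray
    ret_image: np.ndarray
    he_tissue: np.ndarray
    ret_tissue: np.ndarray
    he_bone: np.ndarray | None
    ret_bone: np.ndarray | None
    ret_fat: np.ndarray | None
    phantom: PhantomPair | None


def _load_sample(entry: SampleEntry) -> _SampleData:
    if entry.phantom_spec is not None:
        spec = phantom_spec_from_dict(entry.phantom_spec)
        ph = generate_phantom(spec)
        return _SampleData(
            entry=entry,
            he_image=ph.he_image,
            ret_image=ph.reticulin_image,
            he_tissue=ph.tissue_mask,
            ret_tissue=ph.ret_tissue_mask,
            he_bone=ph.bone_mask,
            ret_bone=ph.ret_bone_mask,
            ret_fat=ph.ret_fat_mask,
            phantom=ph,
        )
    he = iio.imread(entry.he_path)[..., :3]
    ret = iio.imread(entry.reticulin_path)[..., :3]
    masks = entry.mask_paths or {}

    def read_mask(key):
        return iio.imread(masks[key]) > 127 if key in masks else None

    he_tissue = read_mask("he_tissue")
    ret_tissue = read_mask("ret_tissue")
    return _SampleData(
        entry=entry,
        he_image=he,
        ret_image=ret,
        he_tissue=he_tissue if he_tissue is not None else compute_tissue_mask(he),
        ret_tissue=ret_tissue if ret_tissue is not None else compute_tissue_mask(ret),
        he_bone=read_mask("he_bone"),
        ret_bone=read_mask("ret_bone"),
        ret_fat=read_mask("ret_fat"),
        phantom=None,
    )


def _phantom_teacher(data: _SampleData, table: pd.DataFrame) -> np.ndarray:
    """Per-tile labels from the phantom's reticulin-frame latent field —
    the stand-in for a pretrained reticulin-based scoring model."""
    if data.phantom is None:
        raise ValueError(
            f"sample {data.entry.sample_id} is not a phantom; supply a teacher callable"
        )
    f = data.phantom.ret_fibrosis_field
    labels = np.empty(len(table))
    for pos, (x0, y0, ts) in enumerate(zip(table["x0"], table["y0"], table["tile_size"])):
        labels[pos] = float(
            f[int(y0) : int(y0) + int(ts), int(x0) : int(x0) + int(ts)].mean(dtype=np.float64)
        )
    return labels


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def prepare_samples(
    manifest: PairManifest,
    config: PipelineConfig,
    teacher=None,
    out: Path | None = None,
) -> list[dict]:
    """Load/simulate each sample, register the stain pair, tile the
    reticulin frame, cut matched H&E tiles, attach teacher labels and
    equalise.  Writes per-sample affine/tile artefacts when ``out`` is set.
    """
    manifest.validate_paths()
    teacher = teacher or _phantom_teacher
    samples: list[dict] = []
    for entry in manifest.samples:
        sdir = None
        if out is not None:
            sdir = out / entry.sample_id
            sdir.mkdir(exist_ok=True)
        try:
            data = _load_sample(entry)
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise StageError("load", entry.sample_id, e) from e
        try:
            reg = estimate_affine(data.ret_tissue, data.he_tissue)
            if sdir is not None:
                (sdir / "affine.json").write_text(reg.to_json())
        except Exception as e:
            raise StageError("register", entry.sample_id, e) from e
        try:
            table = extract_tiles(
                data.ret_image,
                data.ret_tissue,
                bone_mask=data.ret_bone,
                fat_mask=data.ret_fat,
                tile_size=config.tile_size,
                min_tissue_fraction=config.min_tissue_fraction,
            )
            if len(table) == 0:
                raise ValueError("no tiles inside tissue")
            if sdir is not None:
                table.to_csv(sdir / "tiles.csv", index=False)
            pairs = pair_tiles(table, reg.transform, data.he_image)
        except StageError:
            raise
        except Exception as e:
            raise StageError("tile", entry.sample_id, e) from e
        try:
            labels = np.asarray(teacher(data, table), dtype=float)
        except Exception as e:
            raise StageError("label", entry.sample_id, e) from e

        kept = {p.index for p in pairs}
        mask = table["index"].isin(kept).to_numpy()
        table_kept = table.loc[mask].reset_index(drop=True)
        labels_kept = labels[mask]
        he_tiles = np.stack([p.dst_tile for p in pairs])
        he_tiles_eq = np.stack([equalize_channels(t) for t in he_tiles])
        samples.append(
            {
                "entry": entry,
                "data": data,
                "table": table_kept,
                "pairs": pairs,
                "labels": labels_kept,
                "tiles_eq": he_tiles_eq,
                "dir": sdir,
            }
        )
    return samples


def train_from_samples(samples: list[dict], config: PipelineConfig):
    """Train the ranking model on the first ``ceil(train_fraction * n)``
    samples (manifest order); returns the calibrated model."""
    n_train = max(1, int(np.ceil(config.train_fraction * len(samples))))
    train_samples = samples[:n_train]
    if config.apply_composition_filter_for_training:
        sel = [s["table"]["analysable"].to_numpy(bool) for s in train_samples]
    else:
        sel = [np.ones(len(s["table"]), dtype=bool) for s in train_samples]
    train_tiles = np.concatenate([s["tiles_eq"][m] for s, m in zip(train_samples, sel)])
    train_labels = np.concatenate([s["labels"][m] for s, m in zip(train_samples, sel)])
    try:
        pairs_idx = make_training_pairs(train_labels, config.train.delta, seed=config.seed)
        model = train_ranking_model(pairs_idx, train_tiles, config.train)
    except Exception as e:
        raise StageError("train", "<cohort>", e) from e
    return model, n_train


def run_end_to_end(
    manifest: PairManifest,
    config: PipelineConfig,
    out_dir,
    teacher=None,
) -> Path:
    """Execute the whole pipeline over a manifest; returns the run directory.

    ``teacher`` is a callable ``(sample_data, tile_table) -> labels``; by
    default phantom samples are labelled from their own latent field.  The
    first ``ceil(train_fraction * n_samples)`` manifest rows (manifest order)
    form the training set; scoring, QC and subsampling run on every sample.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: list[str] = []
    from fractions import Fraction

    fractions = [Fraction(f) for f in config.subsample_fractions]

    samples = prepare_samples(manifest, config, teacher=teacher, out=out)
    for s in samples:
        artefacts += [str(s["dir"] / "affine.json"), str(s["dir"] / "tiles.csv")]
    model, n_train = train_from_samples(samples, config)
    model.save(out / "model.npz")
    artefacts.append(str(out / "model.npz"))

    # ---- per-sample scoring, rendering, QC, subsampling ------------
    qc_report = QCReport()
    ret_qc = QCReport()
    results = {}
    groups = {}
    for s in samples:
        entry: SampleEntry = s["entry"]
        data: _SampleData = s["data"]
        sdir: Path = s["dir"]
        try:
            analysable = s["table"]["analysable"].to_numpy(bool)
            table_a = s["table"].loc[analysable].reset_index(drop=True)
            tiles_a = s["tiles_eq"][analysable]
            if len(table_a) == 0:
                raise ValueError("no analysable tiles")
            # CIF map lives in the H&E frame: use the paired tile coordinates
            dst_coords = {p.index: (p.dst_x0, p.dst_y0) for p in s["pairs"]}
            table_he = table_a.copy()
            table_he["x0"] = [dst_coords[i][0] for i in table_a["index"]]
            table_he["y0"] = [dst_coords[i][1] for i in table_a["index"]]
            cif_map = predict_cif(model, tiles_a, table_he, data.he_image.shape[:2])
            cif_map.to_csv(sdir / "cif.csv")
            heat = render_heatmap(cif_map, data.he_image)
            iio.imwrite(sdir / "heatmap.png", heat)
        except StageError:
            raise
        except Exception as e:
            raise StageError("predict", entry.sample_id, e) from e
        try:
            he_bone = data.he_bone if data.he_bone is not None else np.zeros_like(data.he_tissue)
            ret_bone = data.ret_bone if data.ret_bone is not None else np.zeros_like(data.ret_tissue)
            qc_report.add_slide(
                entry.sample_id, data.he_image, data.he_tissue, he_bone, entry.mpp, s["table"]
            )
            ret_qc.add_slide(
                entry.sample_id, data.ret_image, data.ret_tissue, ret_bone, entry.mpp, s["table"]
            )
        except Exception as e:
            raise StageError("qc", entry.sample_id, e) from e
        try:
            res = deviation_curve(
                cif_map,
                fractions=fractions,
                draws_per_fraction=config.subsample_draws,
                seed=config.seed,
                threshold=config.heterogeneity_threshold,
            )
            (sdir / "subsample.json").write_text(res.to_json())
            results[entry.sample_id] = res
            groups[entry.sample_id] = entry.group
        except Exception as e:
            raise StageError("subsample", entry.sample_id, e) from e
        artefacts += [str(sdir / "cif.csv"), str(sdir / "heatmap.png"), str(sdir / "subsample.json")]

    # ---- cohort-level outputs --------------------------------------
    cohort = {}
    if len(samples) >= 2:
        cohort["colour_variation_he"] = colour_variation(np.array(qc_report.dominant_rgb))
        cohort["colour_variation_ret"] = colour_variation(np.array(ret_qc.dominant_rgb))
        cohort["colour_dispersion_ret_vs_he"] = compare_dispersion(
            np.array(ret_qc.dominant_rgb), np.array(qc_report.dominant_rgb), seed=config.seed
        )
        cohort["bone_area_ret_vs_he"] = paired_comparison(
            ret_qc.bone_area_mm2, qc_report.bone_area_mm2
        )
    qc_report.cohort = cohort
    (out / "qc_he.json").write_text(qc_report.to_json())
    (out / "qc_reticulin.json").write_text(ret_qc.to_json())
    adequacy = cohort_adequacy_summary(results, groups)
    adequacy.to_csv(out / "adequacy.csv", index=False)
    artefacts += [str(out / "qc_he.json"), str(out / "qc_reticulin.json"), str(out / "adequacy.csv")]

    # held-out ranking accuracy when a validation split exists
    eval_metrics = {}
    if n_train < len(samples):
        val = samples[n_train:]
        val_tiles = np.concatenate([s["tiles_eq"] for s in val])
        val_labels = np.concatenate([s["labels"] for s in val])
        try:
            eval_metrics["val_pairwise_accuracy"] = pairwise_prediction_accuracy(
                model.scores(val_tiles), val_labels, config.train.delta
            )
        except ValueError:
            eval_metrics["val_pairwise_accuracy"] = None

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples": len(samples),
        "n_train_samples": n_train,
        "training_curve": model.history,
        "training_curve_crc32": model.history_hash(),
        "eval": eval_metrics,
        "artefacts": sorted(artefacts),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
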