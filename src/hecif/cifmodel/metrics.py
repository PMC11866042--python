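"""Evaluation metrics for continuous fibrosis scores."""

from __future__ import annotations

import numpy as np

from .model import CIFMap

__all__ = ["pairwise_prediction_accuracy", "mean_cif_difference"]


def pairwise_prediction_accuracy(
    pred_scores: np.ndarray, true_labels: np.ndarray, delta: float = 0.1
) -> float:
    """Fraction of delta-separated ordered pairs ranked concordantly.

    For every ordered pair (i, j) with ``true_i - true_j >= delta`` the
    prediction is concordant when ``pred_i > pred_j``; tied predictions
    receive half credit (the AUC convention), so an uninformative constant
    predictor scores 0.5 rather than 0.  Raises when no pair qualifies.
    """
    pred = np.asarray(pred_scores, dtype=float)
    true = np.asarray(true_labels, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred_scores and true_labels must have equal length")
    hi, lo = np.nonzero(true[:, None] - true[None, :] >= delta)
    if hi.size == 0:
        raise ValueError(f"no pair with label gap >= {delta}")
    d = pred[hi] - pred[lo]
    return float(((d > 0).sum() + 0.5 * (d == 0).sum()) / hi.size)


def mean_cif_difference(map_a: CIFMap, map_b: CIFMap) -> tuple[float, float]:
    """Mean and SD of |CIF_a - CIF_b| over the tiles shared by two maps.

    Used to compare scores from two models (e.g. H&E-derived vs teacher) on
    the same slide.  Raises if the maps share no tile indices.
    """
    a = map_a.scores.set_index("index")["cif"]
    b = map_b.scores.set_index("index")["cif"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("CIF maps share no tile indices")
    diff = np.abs(a.loc[shared].to_numpy() - b.loc[shared].to_numpy())
    return float(diff.mean()), float(diff.std(ddof=0))
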