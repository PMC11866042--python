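"""Fibrosis heterogeneity and biopsy adequacy by spatial subsampling.

A trephine biopsy samples a small region of a spatially heterogeneous
marrow, so a whole-slide fibrosis score computed from a fraction of the
analysable area can deviate from the full-slide score.  This module
emulates smaller biopsies by drawing contiguous subsets of the analysable
tiles at fixed area fractions (2/15 ... 10/15 of the analysable area by
default), recording each subset's mean CIF, and classifying a slide as
*heterogeneous* when any smallest-fraction subsample deviates from the
whole-sample CIF by strictly more than 0.1.

A subsampled region is realised as a randomly centred patch: a centre tile
is drawn uniformly among the analysable tiles and the region grows by
repeatedly adding the analysable tile whose centre is nearest (Euclidean,
ties by tile index) until the target tile count — round(fraction x N) — is
reached.  Contiguity across tissue gaps is not enforced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .cifmodel import CIFMap

__all__ = [
    "DEFAULT_FRACTIONS",
    "SubsampleResult",
    "draw_subsample",
    "deviation_curve",
    "classify_heterogeneity",
    "cohort_adequacy_summary",
]

DEFAULT_FRACTIONS = (
    Fraction(2, 15), Fraction(4, 15), Fraction(6, 15), Fraction(8, 15), Fraction(10, 15)
)
DEVIATION_THRESHOLD = 0.1


def _target_count(fraction: float, n: int) -> int:
    k = int(round(float(fraction) * n))
    return max(k, 1)


def draw_subsample(
    cif_map: CIFMap,
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Indices (positions in the map's table) of one subsampled region.

    The centre tile is uniform over the map's tiles; the region is the
    ``round(fraction * N)`` tiles nearest the centre (ties broken by tile
    index).  ``fraction`` must lie in (0, 1]; the target count must not
    exceed the number of available tiles.
    """
    if not 0 < float(fraction) <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(cif_map.scores)
    if n == 0:
        raise ValueError("empty CIF map")
    k = _target_count(fraction, n)
    if k > n:
        raise ValueError(f"target count {k} exceeds available tiles {n}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    centre_pos = int(rng.integers(0, n))
    return nearest_tiles(cif_map, centre_pos, k)


def nearest_tiles(cif_map: CIFMap, centre_pos: int, k: int) -> np.ndarray:
    """The ``k`` tiles nearest the centre tile (Euclidean between tile
    centres, ties by tile index), including the centre itself."""
    centres = cif_map.tile_centres()
    d = np.linalg.norm(centres - centres[centre_pos], axis=1)
    tie_break = cif_map.scores["index"].to_numpy()
    order = np.lexsort((tie_break, d))
    return np.sort(order[:k])


@dataclass
class SubsampleResult:
    """Deviation curves of one slide plus the heterogeneity call."""

    fractions: list
    whole_sample_cif: float
    subsample_means: dict = field(default_factory=dict)  # str(fraction) -> list
    max_deviation: dict = field(default_factory=dict)    # str(fraction) -> float
    draws_per_fraction: int = 20
    seed: int = 0
    threshold: float = DEVIATION_THRESHOLD
    classification: str = ""

    def smallest_fraction_key(self) -> str:
        return str(min(self.fractions, key=float))

    def to_json(self) -> str:
        d = asdict(self)
        d["fractions"] = [str(f) for f in self.fractions]
        return json.dumps(d, indent=2)


def deviation_curve(
    cif_map: CIFMap,
    fractions=DEFAULT_FRACTIONS,
    draws_per_fraction: int = 20,
    seed: int = 0,
    threshold: float = DEVIATION_THRESHOLD,
) -> SubsampleResult:
    """Run the subsampling experiment on one slide.

    For every fraction, ``draws_per_fraction`` independent regions are drawn;
    each region's mean CIF and the maximum absolute deviation from the
    whole-sample CIF are recorded.  Fully seeded and reproducible.
    """
    if draws_per_fraction < 1:
        raise ValueError("draws_per_fraction must be >= 1")
    whole = cif_map.aggregate
    cif = cif_map.scores["cif"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    result = SubsampleResult(
        fractions=list(fractions),
        whole_sample_cif=whole,
        draws_per_fraction=draws_per_fraction,
        seed=seed,
        threshold=threshold,
    )
    for frac in fractions:
        means = []
        for _ in range(draws_per_fraction):
            sel = draw_subsample(cif_map, float(frac), rng)
            means.append(float(cif[sel].mean()))
        result.subsample_means[str(frac)] = means
        max_dev = float(np.max(np.abs(np.array(means) - whole)))
        # snap summation noise to an exact zero (uniform maps, fraction 1.0)
        result.max_deviation[str(frac)] = 0.0 if max_dev < 1e-12 else max_dev
    result.classification = classify_heterogeneity(result, threshold)
    return result


def classify_heterogeneity(result: SubsampleResult, threshold: float = DEVIATION_THRESHOLD) -> str:
    """'heterogeneous' iff any smallest-fraction subsample deviates from the
    whole-sample CIF by strictly more than ``threshold``; else 'homogeneous'."""
    key = result.smallest_fraction_key()
    if key not in result.subsample_means:
        raise ValueError("smallest-fraction draws missing from result")
    means = np.asarray(result.subsample_means[key], dtype=float)
    dev = np.abs(means - result.whole_sample_cif)
    return "heterogeneous" if bool((dev > threshold).any()) else "homogeneous"


def cohort_adequacy_summary(results: dict, groups: dict) -> pd.DataFrame:
    """Per-group mean of per-slide max deviation at each fraction.

    ``results`` maps slide id -> SubsampleResult, ``groups`` maps slide id ->
    group label.  Adds a per-group Spearman trend statistic (deviation vs
    fraction; negative rho = deviation shrinks as the sampled area grows).
    """
    if not results:
        raise ValueError("no subsample results supplied")
    rows = []
    for sid, res in results.items():
        for frac in res.fractions:
            rows.append(
                {
                    "slide_id": sid,
                    "group": groups.get(sid, "all"),
                    "fraction": float(frac),
                    "max_deviation": res.max_deviation[str(frac)],
                }
            )
    df = pd.DataFrame(rows)
    for g, sub in df.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
    table = (
        df.groupby(["group", "fraction"], as_index=False)["max_deviation"]
        .mean()
        .sort_values(["group", "fraction"])
        .reset_index(drop=True)
    )
    trends = {}
    for g, sub in table.groupby("group"):
        if sub["fraction"].nunique() > 1 and sub["max_deviation"].nunique() > 1:
            rho = stats.spearmanr(sub["fraction"], sub["max_deviation"]).statistic
        else:
            rho = 0.0
        trends[g] = float(rho)
    table.attrs["trend_spearman"] = trends
    return table
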