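"""Ranking model: pair construction, training mechanics, scoring, metrics,
heatmap rendering.  Heavy rank-recovery runs live in the acceptance suite."""

import numpy as np
import pandas as pd
import pytest

from hecif.cifmodel import (
    CIFMap,
    RankingModel,
    RankingTrainConfig,
    make_training_pairs,
    mean_cif_difference,
    pairwise_prediction_accuracy,
    predict_cif,
    render_heatmap,
    train_ranking_model,
)

TINY = RankingTrainConfig(channels=(4, 8), input_px=16, epochs=3, lr=3e-3, batch_pairs=8, seed=0)


def _texture_tiles(labels, size=16, seed=0):
    """Tiles whose dark-speck density tracks the label."""
    rng = np.random.default_rng(seed)
    tiles = []
    for lab in labels:
        t = np.full((size, size, 3), 220, dtype=np.uint8)
        n = int(lab * size * size * 0.4)
        xs = rng.integers(0, size, n)
        ys = rng.integers(0, size, n)
        t[ys, xs] = (60, 40, 50)
        tiles.append(t)
    return np.stack(tiles)


class TestMakeTrainingPairs:
    def test_single_qualifying_pair(self):
        pairs = make_training_pairs(np.array([0.1, 0.9]), delta=0.2, exhaustive=True)
        assert pairs.tolist() == [[1, 0]]  # higher first

    def test_all_equal_labels_error(self):
        with pytest.raises(ValueError, match="smaller delta"):
            make_training_pairs(np.array([0.4, 0.4, 0.4]), delta=0.1)

    def test_exhaustive_count_matches_brute_force(self):
        rng = np.random.default_rng(5)
        labels = rng.uniform(0, 1, 100)
        pairs = make_training_pairs(labels, delta=0.3, exhaustive=True)
        brute = sum(
            1 for i in range(100) for j in range(100) if labels[i] - labels[j] >= 0.3
        )
        assert len(pairs) == brute
        assert np.all(labels[pairs[:, 0]] - labels[pairs[:, 1]] >= 0.3)

    def test_sampled_pairs_deterministic(self):
        labels = np.linspace(0, 1, 20)
        a = make_training_pairs(labels, 0.1, seed=3, n_pairs=50)
        b = make_training_pairs(labels, 0.1, seed=3, n_pairs=50)
        assert np.array_equal(a, b)


class TestTraining:
    def test_loss_decreases_on_repeated_pair(self):
        tiles = _texture_tiles([0.1, 0.9])
        pairs = np.array([[1, 0]] * 8)
        model = train_ranking_model(pairs, tiles, TINY)
        assert model.history[-1] < model.history[0]

    def test_nan_divergence_aborts(self, monkeypatch):
        # a non-finite loss must abort with the config in the message
        import hecif.cifmodel.model as mdl

        class _NanNet:
            def forward(self, x):
                return np.full((x.shape[0], 1), np.nan, dtype=np.float32)

            def backward(self, d):  # pragma: no cover - never reached
                raise AssertionError

            def parameters(self):
                return []

        monkeypatch.setattr(mdl, "_build_network", lambda cfg, rng: _NanNet())
        monkeypatch.setattr(mdl.Adam, "__init__", lambda self, net, lr: None)
        with pytest.raises(RuntimeError, match="diverged"):
            train_ranking_model(np.array([[1, 0]] * 4), _texture_tiles([0.1, 0.9]), TINY)

    def test_training_deterministic(self):
        tiles = _texture_tiles(np.linspace(0, 1, 12))
        pairs = make_training_pairs(np.linspace(0, 1, 12), 0.2, seed=0, n_pairs=40)
        m1 = train_ranking_model(pairs, tiles, TINY)
        m2 = train_ranking_model(pairs, tiles, TINY)
        assert m1.history == m2.history
        assert m1.history_hash() == m2.history_hash()
        assert np.array_equal(m1.scores(tiles), m2.scores(tiles))

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_ranking_model(np.empty((0, 2), int), _texture_tiles([0.5]), TINY)


@pytest.fixture(scope="module")
def trained():
    labels = np.linspace(0, 1, 16)
    tiles = _texture_tiles(labels)
    pairs = make_training_pairs(labels, 0.2, seed=1, n_pairs=60)
    return train_ranking_model(pairs, tiles, TINY), tiles, labels


class TestCalibration:

    def test_calibration_endpoints(self, trained):
        model, tiles, _ = trained
        raw = model.raw_scores(tiles)
        scores = model.scores(tiles)
        assert scores[np.argmin(raw)] == 0.0
        assert scores[np.argmax(raw)] == 1.0
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_uncalibrated_model_errors(self, trained):
        model, tiles, _ = trained
        bare = RankingModel(model.net, model.config)
        with pytest.raises(ValueError, match="uncalibrated"):
            bare.scores(tiles)

    def test_save_load_roundtrip(self, trained, tmp_path):
        model, tiles, _ = trained
        model.save(tmp_path / "model.npz")
        back = RankingModel.load(tmp_path / "model.npz")
        assert back.config == model.config
        assert np.array_equal(back.scores(tiles), model.scores(tiles))


class TestPairwiseAccuracy:
    def test_perfect_monotone_is_one(self):
        labels = np.linspace(0, 1, 10)
        assert pairwise_prediction_accuracy(labels, labels, 0.1) == 1.0

    def test_reversed_is_zero(self):
        labels = np.linspace(0, 1, 10)
        assert pairwise_prediction_accuracy(-labels, labels, 0.1) == 0.0

    def test_constant_prediction_is_half(self):
        labels = np.linspace(0, 1, 10)
        assert pairwise_prediction_accuracy(np.zeros(10), labels, 0.1) == 0.5

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        labels = rng.uniform(0, 1, 60)
        pred = rng.uniform(0, 1, 60)
        acc = pairwise_prediction_accuracy(pred, labels, 0.15)
        num = den = 0.0
        for i in range(60):
            for j in range(60):
                if labels[i] - labels[j] >= 0.15:
                    den += 1
                    if pred[i] > pred[j]:
                        num += 1
                    elif pred[i] == pred[j]:
                        num += 0.5
        assert acc == pytest.approx(num / den)

    def test_no_qualifying_pairs_error(self):
        with pytest.raises(ValueError):
            pairwise_prediction_accuracy(np.ones(4), np.full(4, 0.5), 0.1)


def _cif_map(values, n_side=None, tile=64):
    n = len(values)
    n_side = n_side or int(np.ceil(np.sqrt(n)))
    df = pd.DataFrame(
        {
            "index": range(n),
            "x0": [(i % n_side) * tile for i in range(n)],
            "y0": [(i // n_side) * tile for i in range(n)],
            "tile_size": [tile] * n,
            "cif": values,
        }
    )
    return CIFMap(df, (n_side * tile, n_side * tile))


class TestCIFMapAndDifference:
    def test_aggregate_is_mean(self):
        m = _cif_map([0.0, 0.5, 1.0, 0.5])
        assert m.aggregate == pytest.approx(0.5)

    def test_scores_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _cif_map([0.5, 1.2])

    def test_self_difference_zero(self):
        m = _cif_map([0.2, 0.4, 0.6, 0.8])
        assert mean_cif_difference(m, m) == (0.0, 0.0)

    def test_constant_offset(self):
        a = _cif_map([0.2, 0.4, 0.6, 0.3])
        b = _cif_map([0.3, 0.5, 0.7, 0.4])
        mean, sd = mean_cif_difference(a, b)
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(2)
        a = _cif_map(rng.uniform(0, 1, 25))
        b = _cif_map(rng.uniform(0, 1, 25))
        mean, sd = mean_cif_difference(a, b)
        diffs = [
            abs(x - y) for x, y in zip(a.scores["cif"], b.scores["cif"])
        ]
        assert mean == pytest.approx(np.mean(diffs))
        assert sd == pytest.approx(np.std(diffs))

    def test_disjoint_maps_error(self):
        a = _cif_map([0.1, 0.2])
        b = _cif_map([0.1, 0.2])
        b.scores["index"] = [10, 11]
        with pytest.raises(ValueError):
            mean_cif_difference(a, b)


class TestHeatmap:
    def test_uniform_extremes(self):
        from matplotlib import colormaps

        img = np.zeros((128, 128, 3), dtype=np.uint8)
        for val in (0.0, 1.0):
            m = _cif_map([val] * 4, n_side=2)
            out = render_heatmap(m, img, legend=False)
            expected = (np.array(colormaps["viridis"](val)[:3]) * 255).round().astype(np.uint8)
            assert np.all(out.reshape(-1, 3) == expected)

    def test_checkerboard_exact(self):
        from matplotlib import colormaps

        img = np.zeros((128, 128, 3), dtype=np.uint8)
        m = _cif_map([0.0, 1.0, 1.0, 0.0], n_side=2)
        out = render_heatmap(m, img, legend=False)
        lo = (np.array(colormaps["viridis"](0.0)[:3]) * 255).round().astype(np.uint8)
        hi = (np.array(colormaps["viridis"](1.0)[:3]) * 255).round().astype(np.uint8)
        assert np.all(out[:64, :64] == lo) and np.all(out[64:, 64:] == lo)
        assert np.all(out[:64, 64:] == hi) and np.all(out[64:, :64] == hi)

    def test_legend_extends_canvas(self):
        img = np.zeros((128, 128, 3), dtype=np.uint8)
        out = render_heatmap(_cif_map([0.5] * 4, n_side=2), img, legend=True, legend_width=40)
        assert out.shape == (128, 168, 3)

    def test_geometry_mismatch_error(self):
        with pytest.raises(ValueError, match="geometry"):
            render_heatmap(_cif_map([0.5] * 4, n_side=2), np.zeros((64, 64, 3), dtype=np.uint8))


def test_predict_cif_assembles_map():
    labels = np.linspace(0, 1, 9)
    tiles = _texture_tiles(labels)
    pairs = make_training_pairs(labels, 0.2, seed=2, n_pairs=40)
    model = train_ranking_model(pairs, tiles, TINY)
    table = pd.DataFrame(
        {
            "index": range(9),
            "x0": [(i % 3) * 16 for i in range(9)],
            "y0": [(i // 3) * 16 for i in range(9)],
            "tile_size": [16] * 9,
        }
    )
    m = predict_cif(model, tiles, table, (48, 48))
    assert len(m.scores) == 9
    assert m.scores["cif"].between(0, 1).all()
    assert m.aggregate == pytest.approx(m.scores["cif"].mean())
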