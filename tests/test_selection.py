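"""CWINCA selection: normalization, bounds, CV loss, and the full search."""

import numpy as np
import pytest

from cwinca.data import LabeledMatrix
from cwinca.nca import NcaConfig
from cwinca.selection import (
    CwincaConfig,
    cumulative_bounds,
    cwinca_select,
    knn_cv_loss,
    make_folds,
    minmax_normalize,
    nested_selection_loss,
)
from cwinca.synthetic import PlantedSpec, make_planted_features

from conftest import brute_knn_fold_loss, brute_size_sweep


class TestMinMaxNormalize:
    def test_direct_formula(self):
        lm = LabeledMatrix(np.array([[1.0], [2.0], [3.0]]), [0, 1, 0])
        out = minmax_normalize(lm, epsilon=1e-8)
        np.testing.assert_allclose(
            out.values[:, 0], [0.0, 0.4999999975, 0.999999995], rtol=1e-12
        )

    def test_constant_column_maps_to_zeros(self):
        lm = LabeledMatrix(np.array([[7.0, 1.0], [7.0, 2.0], [7.0, 3.0]]), [0, 1, 0])
        out = minmax_normalize(lm)
        np.testing.assert_array_equal(out.values[:, 0], np.zeros(3))

    def test_small_epsilon_approaches_affine_map(self):
        lm = LabeledMatrix(np.array([[-2.0], [0.0], [2.0]]), [0, 1, 0])
        out = minmax_normalize(lm, epsilon=1e-12)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0], atol=1e-9)

    def test_labels_and_names_pass_through(self, rng):
        lm = LabeledMatrix(rng.normal(size=(5, 3)), [0, 1, 0, 1, 0], ["a", "b", "c"])
        out = minmax_normalize(lm)
        assert out.feature_names == ["a", "b", "c"]
        np.testing.assert_array_equal(out.labels, lm.labels)
        assert out.values.min() >= 0 and out.values.max() < 1


class TestCumulativeBounds:
    def test_hand_computed_window(self):
        order, cum, start, stop = cumulative_bounds(np.array([0.4, 0.3, 0.2, 0.1]))
        np.testing.assert_array_equal(order, [0, 1, 2, 3])
        np.testing.assert_allclose(cum, [0.4, 0.7, 0.9, 1.0])
        assert (start, stop) == (2, 4)

    def test_zero_weights_fall_back_to_defaults(self):
        # unreachable thresholds: start falls back to 10, stop to d
        _, cum, start, stop = cumulative_bounds(np.zeros(25))
        assert (start, stop) == (10, 25)
        assert (cum == 0).all()

    def test_zero_weight_fallback_clamped_to_d(self):
        _, _, start, stop = cumulative_bounds(np.zeros(6))
        assert (start, stop) == (6, 6)

    def test_ties_break_by_original_position(self):
        order, _, _, _ = cumulative_bounds(np.array([0.5, 0.5, 0.5]))
        np.testing.assert_array_equal(order, [0, 1, 2])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cumulative_bounds(np.array([0.5, -0.1]))

    def test_cumulative_is_monotone_with_final_one(self, rng):
        for _ in range(10):
            w = rng.uniform(0, 1, size=int(rng.integers(1, 30)))
            _, cum, start, stop = cumulative_bounds(w)
            assert (np.diff(cum) >= -1e-12).all()
            assert cum[-1] == pytest.approx(1.0)
            assert 1 <= start <= stop <= w.size


class TestKnnCvLoss:
    def test_well_separated_clusters_have_zero_loss(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, size=(10, 2)), rng.normal(100, 1, size=(10, 2))]
        )
        y = np.array([0] * 10 + [1] * 10)
        assert knn_cv_loss(LabeledMatrix(X, y), CwincaConfig(seed=0)) == 0.0

    def test_conflicting_duplicates_match_brute_force(self):
        # 20 identical points, half labeled A and half B: every prediction is
        # decided purely by the tie rule, which the oracle shares
        X = np.ones((20, 3))
        y = np.array(["A"] * 10 + ["B"] * 10)
        cfg = CwincaConfig(seed=3)
        folds = make_folds(y, cfg.cv_folds, cfg.seed)
        expected = brute_knn_fold_loss(X, y, folds)
        assert knn_cv_loss(LabeledMatrix(X, y), cfg) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_brute_force_exactly(self, seed):
        g = np.random.default_rng(seed)
        X = g.normal(size=(40, 3))
        y = g.integers(0, 2, size=40)
        y[:2] = [0, 1]
        cfg = CwincaConfig(seed=seed)
        folds = make_folds(y, cfg.cv_folds, cfg.seed)
        assert knn_cv_loss(LabeledMatrix(X, y), cfg) == brute_knn_fold_loss(
            X, y, folds
        )

    def test_tiny_class_falls_back_to_plain_kfold(self, caplog):
        X = np.random.default_rng(0).normal(size=(12, 2))
        y = np.array([0] * 11 + [1])
        with caplog.at_level("WARNING"):
            loss = knn_cv_loss(LabeledMatrix(X, y), CwincaConfig(cv_folds=5, seed=0))
        assert 0 <= loss <= 1
        assert "falling back" in caplog.text

    def test_n_below_folds_rejected(self):
        lm = LabeledMatrix(np.eye(4), [0, 1, 0, 1])
        with pytest.raises(ValueError, match="cv_folds"):
            knn_cv_loss(lm, CwincaConfig(cv_folds=10))


class TestCwincaSelect:
    def test_trace_matches_naive_candidate_enumeration(self):
        # recompute every candidate subset's loss with the loop-based oracle
        for seed in range(5):
            data = make_planted_features(
                PlantedSpec(n=50, informative=2, noise=6, class_sep=1.5, seed=seed)
            )
            cfg = CwincaConfig(seed=seed, cv_folds=5)
            trace = cwinca_select(data, cfg, NcaConfig(seed=seed, epochs=15))
            normed = minmax_normalize(data, cfg.epsilon)
            order = [data.feature_names.index(f) for f in trace.ranked_features]
            folds = make_folds(data.labels, cfg.cv_folds, cfg.seed)
            losses, chosen, best = brute_size_sweep(
                normed, order, trace.start_size, trace.stop_size, folds
            )
            assert trace.chosen_size == chosen
            assert trace.best_loss == best
            np.testing.assert_array_equal(trace.losses, losses)

    def test_planted_features_recovered_with_benefit(self):
        recovered = benefited = 0
        for seed in range(10):
            data = make_planted_features(PlantedSpec(seed=seed))
            cfg = CwincaConfig(seed=seed)
            trace = cwinca_select(data, cfg, NcaConfig(seed=seed))
            recovered += {"inf1", "inf2", "inf3"} <= set(trace.selected_features)
            full_loss = knn_cv_loss(minmax_normalize(data, cfg.epsilon), cfg)
            benefited += trace.best_loss <= full_loss
        assert recovered >= 8
        assert benefited >= 8

    def test_single_feature_degenerates_cleanly(self, rng):
        X = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])[:, None]
        y = np.array([0] * 10 + [1] * 10)
        trace = cwinca_select(
            LabeledMatrix(X, y, ["only"]), CwincaConfig(seed=0, cv_folds=5),
            NcaConfig(seed=0, epochs=10),
        )
        assert trace.start_size == trace.stop_size == trace.chosen_size == 1
        assert trace.selected_features == ["only"]

    def test_selected_sets_are_nested_prefixes(self):
        data = make_planted_features(PlantedSpec(n=60, seed=4))
        trace = cwinca_select(
            data, CwincaConfig(seed=4, cv_folds=5), NcaConfig(seed=4, epochs=15)
        )
        for s in range(trace.start_size, trace.stop_size):
            assert trace.ranked_features[:s] == trace.ranked_features[: s + 1][:-1]
        assert trace.selected_features == trace.ranked_features[: trace.chosen_size]

    def test_deterministic_given_seeds(self):
        data = make_planted_features(PlantedSpec(n=60, seed=2))
        args = (CwincaConfig(seed=2, cv_folds=5), NcaConfig(seed=2, epochs=10))
        t1 = cwinca_select(data, *args)
        t2 = cwinca_select(data, *args)
        assert t1.to_dict() == t2.to_dict()


def test_nested_selection_loss_is_a_valid_rate():
    data = make_planted_features(PlantedSpec(n=60, noise=5, seed=1))
    loss = nested_selection_loss(
        data, CwincaConfig(seed=1, cv_folds=3), NcaConfig(seed=1, epochs=10)
    )
    assert 0.0 <= loss <= 1.0


def test_trace_json_round_trip(tmp_path):
    data = make_planted_features(PlantedSpec(n=40, noise=4, seed=0))
    trace = cwinca_select(
        data, CwincaConfig(seed=0, cv_folds=4), NcaConfig(seed=0, epochs=10)
    )
    path = tmp_path / "trace.json"
    trace.to_json(path)
    import json

    doc = json.loads(path.read_text())
    assert doc["chosen_size"] == trace.chosen_size
    assert doc["losses"] == trace.losses.tolist()
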