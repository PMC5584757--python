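import numpy as np
import pytest

from boutondetect.classification import (
    ClassifierParams,
    LabelledFeatureSet,
    classify,
    grid_search,
    load_model,
    save_model,
    scale_scores,
    select_threshold,
    train,
)
from boutondetect.gabor_features import GaborConfig
from boutondetect.pipeline import features_from_patches
from boutondetect.synthetic import SceneParams, generate_patches


def _two_clusters(rng, n=100, sep=10.0, dim=12):
    a = rng.normal(0, 1, (n, dim))
    b = rng.normal(sep, 1, (n, dim))
    X = np.vstack([a, b])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return LabelledFeatureSet(X, y)


class TestTrain:
    def test_separable_clusters_reach_full_training_accuracy(self, rng):
        data = _two_clusters(rng)
        model = train(data, split_seed=1)
        pred = model.model.predict(data.features)
        assert np.mean(pred == data.labels) == 1.0

    def test_same_seed_reproduces_predictions(self, rng):
        data = _two_clusters(rng)
        grid = rng.normal(5, 3, (50, 12))
        m1 = train(data, split_seed=3)
        m2 = train(data, split_seed=3)
        np.testing.assert_array_equal(
            classify(m1, grid)[1], classify(m2, grid)[1]
        )

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (20, 12))
        with pytest.raises(ValueError):
            train(LabelledFeatureSet(X, np.ones(20, int)))

    def test_synthetic_patch_validation_accuracy(self, default_model):
        """450 + 450 synthetic patches (seed 7) train to >= 0.9
        validation accuracy."""
        assert default_model.validation_accuracy >= 0.9

    def test_balanced_downsampling(self, rng):
        X = rng.normal(0, 1, (150, 12))
        X[:50] += 8.0
        y = np.r_[np.ones(50, int), np.zeros(100, int)]
        model = train(LabelledFeatureSet(X, y), split_seed=0)
        # 100 balanced -> 80 train, classes near-equal.
        assert sum(model.n_train_per_class.values()) == 80


class TestScaleScores:
    def test_affine_map_examples(self):
        np.testing.assert_allclose(
            scale_scores([-2.0, 0.0, 6.0], (-2.0, 6.0)), [-1.0, -0.5, 1.0]
        )
        assert scale_scores([-2.0], (-2.0, 6.0))[0] == -1.0

    def test_out_of_range_extrapolates(self):
        assert scale_scores([10.0], (-2.0, 6.0))[0] > 1.0

    def test_round_trip_with_inverse(self, rng):
        lo, hi = -3.0, 5.0
        raw = rng.normal(0, 4, 200)
        scaled = scale_scores(raw, (lo, hi))
        back = lo + (scaled + 1) * (hi - lo) / 2
        np.testing.assert_allclose(back, raw, atol=1e-12)

    def test_degenerate_scaler_rejected(self):
        with pytest.raises(ValueError):
            scale_scores([0.0], (1.0, 1.0))


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(0)
    return train(_two_clusters(rng), split_seed=0)


class TestClassify:
    def test_operating_threshold_boundary(self, model):
        # Scores straddling the default threshold -0.0399 split classes.
        feats = np.tile(np.full(12, 5.0), (1, 1))
        labels, scores = classify(model, feats)
        manual = (scores >= -0.0399).astype(int)
        np.testing.assert_array_equal(labels, manual)

    def test_threshold_rule_on_known_scores(self):
        assert (np.array([-0.03]) >= -0.0399).all()  # bouton side
        assert not (np.array([-0.05]) >= -0.0399).any()  # non-bouton side

    def test_positives_monotone_in_threshold(self, model, rng):
        feats = rng.normal(5, 4, (200, 12))
        counts = [
            classify(model, feats, threshold=t)[0].sum()
            for t in np.linspace(-1, 1, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scaling_set_endpoints_map_to_unit_interval(self, model):
        lo, hi = model.scaler
        np.testing.assert_allclose(
            scale_scores([lo, hi], model.scaler), [-1.0, 1.0]
        )

    def test_feature_length_mismatch_rejected(self, model, rng):
        with pytest.raises(ValueError):
            classify(model, rng.normal(0, 1, (5, 7)))


class TestThresholdCalibration:
    def test_calibrated_threshold_maximizes_validation_f1(self, rng):
        data = _two_clusters(rng, sep=3.0)
        model = train(data, split_seed=2, calibrate_threshold=True)
        assert -1.0 <= model.params.threshold <= 1.0

    def test_select_threshold_prefers_larger_on_ties(self):
        scores = np.array([-0.5, 0.5])
        labels = np.array([0, 1])
        t = select_threshold(scores, labels, n_grid=21)
        # Any threshold in (-0.5, 0.5] gives F1 = 1; ties go high.
        assert t == pytest.approx(0.5)


class TestGridSearch:
    def test_single_setting_returned(self, rng):
        data = _two_clusters(rng)
        params = grid_search(data, {"degree": [3], "C": [2.0]}, seed=0)
        assert params.degree == 3 and params.C == 2.0

    def test_tie_break_prefers_smallest_cost(self, rng):
        data = _two_clusters(rng)  # separable: all settings tie at F1=1
        params = grid_search(data, {"degree": [3], "C": [0.1, 1.0, 10.0]}, seed=0)
        assert params.C == 0.1

    def test_selected_setting_beats_every_grid_point(self):
        patches, labels = generate_patches(SceneParams(seed=3), 60)
        X = features_from_patches(patches, GaborConfig())
        data = LabelledFeatureSet(X, labels)
        grid = {"degree": [2, 3], "C": [0.1, 1.0, 10.0]}
        best = grid_search(data, grid, seed=0)
        # Independent re-evaluation loop over the same grid.
        from boutondetect.classification import _binary_f1, _partition

        _, _, X_va, y_va = _partition(data, 0, 0.8, True)
        f1s = {}
        for d in grid["degree"]:
            for C in grid["C"]:
                m = train(data, ClassifierParams(degree=d, C=C), split_seed=0)
                f1s[(d, C)] = _binary_f1(m.model.predict(X_va), y_va)
        assert f1s[(best.degree, best.C)] == max(f1s.values())

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search(_two_clusters(rng), {"degree": [], "C": []})


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        data = _two_clusters(rng)
        model = train(data, split_seed=0)
        path = tmp_path / "model.joblib"
        save_model(path, model)
        again = load_model(path)
        grid = rng.normal(5, 3, (30, 12))
        np.testing.assert_array_equal(classify(model, grid)[1], classify(again, grid)[1])
        assert again.scaler == model.scaler
        assert again.params == model.params

    def test_version_mismatch_fails_loudly(self, tmp_path, rng):
        import joblib

        path = tmp_path / "old.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ValueError, match="version"):
            load_model(path)
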