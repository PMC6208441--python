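"""PCI, phenology metrics, terrain variables, and RF/RFE classification."""

import numpy as np
import pandas as pd
import pytest

from gramirice import classify
from gramirice.synth import SceneConfig, _paddy_curve


def paddy_series(cfg=None, doys=None):
    cfg = cfg or SceneConfig(noise_sd=0.0, cloud_gap_prob=0.0)
    doys = np.arange(1, 366, dtype=float) if doys is None else np.asarray(doys, dtype=float)
    return doys, _paddy_curve(doys, cfg)


class TestPci:
    def test_zero_at_equality(self):
        doy = np.array([140.0, 270.0])
        assert classify.paddy_classification_index(doy, np.array([0.4, 0.4])) == 0.0

    def test_hand_value(self):
        # (0.3 - 0.1) / (0.3 + 0.1) = 0.5 with harvest=0.3, transplant=0.1
        doy = np.array([140.0, 270.0])
        assert classify.paddy_classification_index(doy, np.array([0.1, 0.3])) == pytest.approx(0.5)

    def test_scale_invariance(self):
        doy = np.array([140.0, 270.0])
        a = classify.paddy_classification_index(doy, np.array([0.1, 0.3]))
        b = classify.paddy_classification_index(doy, np.array([0.2, 0.6]))
        assert a == pytest.approx(b)

    def test_anchor_tolerance(self):
        # observation 8 days off is accepted; 9 days off is not
        assert np.isfinite(
            classify.paddy_classification_index(np.array([148.0, 262.0]), np.array([0.1, 0.3]))
        )
        assert np.isnan(
            classify.paddy_classification_index(np.array([149.0, 262.0]), np.array([0.1, 0.3]))
        )

    def test_non_positive_denominator_is_nan(self):
        doy = np.array([140.0, 270.0])
        assert np.isnan(classify.paddy_classification_index(doy, np.array([0.2, -0.2])))

    def test_median_daily_series_reduces_years(self):
        y1 = pd.DataFrame({"doy": [140.0, 270.0], "ndvi": [0.1, 0.3]})
        y2 = pd.DataFrame({"doy": [140.0, 270.0], "ndvi": [0.3, 0.5]})
        y3 = pd.DataFrame({"doy": [140.0, 270.0], "ndvi": [0.2, 0.4]})
        med = classify.median_daily_series([y1, y2, y3])
        assert med["ndvi"].tolist() == [0.2, 0.4]


class TestPhenoMetrics:
    def test_noiseless_recovery(self):
        cfg = SceneConfig(noise_sd=0.0, cloud_gap_prob=0.0)
        doys, curve = paddy_series(cfg)
        m = classify.pheno_metrics(doys, curve)
        true_peak_date = doys[np.argmax(curve)]
        assert abs(m.max_peak_date - true_peak_date) <= 3
        assert abs(m.max_peak_value - curve.max()) <= 0.01
        assert m.max_growth_rate > 0 and m.max_fading_rate > 0
        assert m.max_fading_date > m.max_peak_date

    def test_gap_tolerance(self):
        doys, curve = paddy_series()
        keep = np.random.default_rng(0).random(doys.shape) > 0.3
        m_full = classify.pheno_metrics(doys, curve)
        m_gap = classify.pheno_metrics(doys[keep], curve[keep])
        assert abs(m_gap.max_peak_date - m_full.max_peak_date) <= 3
        assert abs(m_gap.max_peak_value - m_full.max_peak_value) <= 0.02

    def test_too_few_observations_all_nan(self):
        m = classify.pheno_metrics(np.arange(5.0), np.full(5, 0.5))
        assert all(np.isnan(v) for v in m.__dict__.values())

    def test_grid_wrapper_shape(self):
        doys, curve = paddy_series()
        stack = np.vstack([curve, curve * 0.8])
        df = classify.pheno_metrics_grid(doys, stack)
        assert df.shape == (2, 6)
        assert list(df.columns) == classify.PHENO_FEATURES


class TestTerrain:
    def test_flat_dem(self):
        t = classify.terrain_variables(np.full((10, 10), 100.0), 500.0)
        np.testing.assert_allclose(t.slope_deg, 0.0, atol=1e-12)
        assert np.isfinite(t.wetness_index).all()

    def test_tilted_plane_slope(self):
        # 1 m drop per 500 m cell along rows -> slope = atan(1/500)
        dem = 100.0 - np.arange(10)[:, None] * np.ones((1, 10))
        t = classify.terrain_variables(dem, 500.0)
        interior = t.slope_deg[2:-2, 2:-2]
        np.testing.assert_allclose(interior, np.rad2deg(np.arctan(1.0 / 500.0)), rtol=1e-6)

    def test_valley_collects_flow(self):
        # V-shaped valley: centre column is lowest and should be wettest
        x = np.abs(np.arange(11) - 5)[None, :] * 10.0
        dem = x + np.arange(11)[:, None] * 1.0  # slight downstream tilt
        t = classify.terrain_variables(dem, 500.0)
        assert t.wetness_index[5:, 5].mean() > t.wetness_index[5:, 0].mean()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            classify.terrain_variables(np.ones((2, 2)), 500.0)
        with pytest.raises(ValueError):
            classify.terrain_variables(np.full((5, 5), np.nan), 500.0)


def _separable_data(n=120, n_noise=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    signal = y + rng.normal(0, 0.15, n)
    X = np.column_stack([signal] + [rng.normal(0, 1, n) for _ in range(n_noise)])
    names = ["signal"] + [f"noise{i}" for i in range(n_noise)]
    return X, y, names


class TestForest:
    def test_train_classify_round_trip(self):
        X, y, names = _separable_data()
        model = classify.train_classifier(X, y, names, n_trees=50)
        assert (classify.classify_paddy(model, X, names) == y).mean() > 0.95

    def test_grid_stack_input(self):
        X, y, names = _separable_data(n=128)
        model = classify.train_classifier(X, y, names, n_trees=50)
        grid = X.reshape(8, 16, X.shape[1])
        labels = classify.classify_paddy(model, grid)
        assert labels.shape == (8, 16)

    def test_schema_mismatch_rejected(self):
        X, y, names = _separable_data()
        model = classify.train_classifier(X, y, names, n_trees=10)
        with pytest.raises(ValueError):
            classify.classify_paddy(model, X, feature_names=list(reversed(names)))
        with pytest.raises(ValueError):
            classify.classify_paddy(model, X[:, :2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify.train_classifier(np.ones((10, 2)), np.zeros(10))

    def test_holdout_accuracy_separable(self):
        X, y, _ = _separable_data()
        assert classify.holdout_accuracy(X, y, n_trees=50) > 0.95


class TestRfe:
    def test_noise_features_eliminated_first(self):
        X, y, names = _separable_data()
        r = classify.rfe_rank(X, y, names, n_trees=50, evaluate_subsets=False)
        assert r["ranking"][0] == "signal"

    def test_deterministic_under_seed(self):
        X, y, names = _separable_data()
        a = classify.rfe_rank(X, y, names, n_trees=50, n_repeats=1, seed=3)
        b = classify.rfe_rank(X, y, names, n_trees=50, n_repeats=1, seed=3)
        assert a == b

    def test_ranking_is_permutation(self):
        X, y, names = _separable_data()
        r = classify.rfe_rank(X, y, names, n_trees=20, evaluate_subsets=False)
        assert sorted(r["ranking"]) == sorted(names)

    def test_subset_selection_contains_signal(self):
        X, y, names = _separable_data()
        r = classify.rfe_rank(X, y, names, n_trees=50, n_folds=5, n_repeats=1, cv_trees=50)
        assert "signal" in r["selected"]
        assert set(r["cv_accuracy"]) == set(range(1, len(names) + 1))

    def test_name_mismatch_rejected(self):
        X, y, names = _separable_data()
        with pytest.raises(ValueError):
            classify.rfe_rank(X, y, names[:-1], n_trees=10)
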