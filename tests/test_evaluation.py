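"""Metric definitions, family comparison and the correlation screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budcast import compare_families, compute_metrics, correlation_screen
from budcast.evaluation import correlation_table
from budcast.regressor import fit, linear_partition, predict_batch

series = st.lists(
    st.floats(min_value=-1e5, max_value=1e5, allow_nan=False, allow_subnormal=False).filter(
        lambda v: v == 0 or abs(v) > 1e-6  # keep |o| away from ~0 so MAPE stays finite
    ),
    min_size=2,
    max_size=40,
)


class TestComputeMetrics:
    def test_identity_series_perfect_scores(self):
        r = compute_metrics([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert (r.r2, r.mae, r.mse, r.rmse, r.msd, r.mape) == (1.0, 0, 0, 0, 0, 0)

    def test_hand_arithmetic_example(self):
        r = compute_metrics([100.0, 110.0, 120.0], [110.0, 100.0, 130.0])
        assert r.mae == pytest.approx(10.0)
        assert r.mse == pytest.approx(100.0)
        assert r.rmse == pytest.approx(10.0)
        assert r.msd == pytest.approx(-10.0 / 3.0)

    def test_against_sklearn_reference(self):
        from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

        rng = np.random.default_rng(0)
        o = rng.uniform(10, 400, 50)
        p = o + rng.normal(0, 25, 50)
        r = compute_metrics(p, o)
        assert r.r2 == pytest.approx(r2_score(o, p), rel=1e-12)
        assert r.mae == pytest.approx(mean_absolute_error(o, p), rel=1e-12)
        assert r.mse == pytest.approx(mean_squared_error(o, p), rel=1e-12)

    def test_constant_observed_degenerate_not_nan(self):
        r = compute_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r.r2 is None
        assert "zero variance" in r.degenerate_reason
        assert np.isfinite(r.mae)

    def test_zero_observed_mape_undefined_other_metrics_kept(self):
        r = compute_metrics([1.0, 2.0], [0.0, 4.0])
        assert r.mape is None
        assert r.mae == pytest.approx(1.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=100, deadline=None)
    @given(obs=series, scale=st.floats(min_value=0.01, max_value=100))
    def test_metric_identities(self, obs, scale):
        rng = np.random.default_rng(1)
        o = np.asarray(obs)
        p = o + rng.normal(0, 1, len(o))
        r = compute_metrics(p, o)
        assert r.rmse**2 == pytest.approx(r.mse, rel=1e-9)
        assert -r.mae - 1e-12 <= r.msd <= r.mae + 1e-12
        if r.mape is not None:
            scaled = compute_metrics(p * scale, o * scale)
            assert scaled.mape == pytest.approx(r.mape, rel=1e-9)


class TestCompareFamilies:
    def test_deterministic_given_seed(self, dataset):
        a = compare_families(dataset, seed=5)
        b = compare_families(dataset, seed=5)
        assert a.equals(b)
        assert list(a.index) == [
            "decision_tree",
            "random_forest_classifier",
            "random_forest_regression",
            "tree_ensemble_classifier",
            "tree_ensemble_regression",
            "gradient_boosted_trees_classifier",
            "gradient_boosted_trees_regression",
        ]

    def test_single_family_equals_direct_chain(self, dataset, features):
        table = compare_families(dataset, seed=5, families=("tree_ensemble_regression",))
        train, test = linear_partition(features, 0.8)
        model = fit("tree_ensemble_regression", train, seed=5)
        pred = predict_batch(model, test)
        direct = compute_metrics(pred["bud_days"], test["bud_days"])
        row = table.loc["tree_ensemble_regression"]
        assert row["r2"] == pytest.approx(direct.r2)
        assert row["rmse"] == pytest.approx(direct.rmse)

    def test_noise_free_linear_target_is_learnable(self):
        # BUD an exact step function of one feature, test rows on the training grid
        from budcast.synthetic import GroundTruthSpec, generate_stability_dataset

        truth = GroundTruthSpec(
            intercept_days=100.0,
            logp_effect=0.0,
            excipient_offsets={},
            temperature_effect=-2.0,
            content_effect=0.0,
            noise_sd=0.0,
        )
        ds = generate_stability_dataset(200, truth, seed=0, n_apis=5)
        table = compare_families(ds, seed=0, families=("tree_ensemble_regression",))
        assert table.loc["tree_ensemble_regression", "r2"] > 0.95


class TestCorrelationScreen:
    def test_parameter_identical_to_prediction(self, features):
        pred = features["logp"].to_numpy(dtype=float)
        rows = {c.parameter: c for c in correlation_screen(features, pred)}
        assert rows["logp"].r == pytest.approx(1.0)
        assert rows["logp"].p < 1e-10
        assert rows["logp"].significant

    def test_exact_linearity_three_points(self, features):
        sub = features.head(3).copy()
        sub["logp"] = [1.0, 2.0, 3.0]
        rows = {c.parameter: c for c in correlation_screen(sub, [2.0, 4.0, 6.0])}
        assert rows["logp"].r == pytest.approx(1.0)

    def test_27_rows_and_zero_variance_marked_undefined(self, features):
        sub = features.copy()
        sub["hbd"] = 2  # force zero variance
        rows = correlation_screen(sub, np.arange(len(sub), dtype=float))
        assert len(rows) == 27
        by_name = {c.parameter: c for c in rows}
        assert by_name["hbd"].undefined

    def test_agrees_with_brute_force_pearson(self, features):
        rng = np.random.default_rng(2)
        pred = rng.uniform(10, 500, len(features))
        for row in correlation_screen(features, pred):
            if row.r is None:
                continue
            from budcast.evaluation import _numeric_parameter

            x = _numeric_parameter(features, row.parameter)
            xc, yc = x - x.mean(), pred - pred.mean()
            r_ref = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert row.r == pytest.approx(r_ref, abs=1e-12)

    def test_fixture_pipeline_logp_screen_tracks_observed_association(self, dataset, features):
        # the screened LogP correlation with predicted BUD is defined and
        # carries the same sign as the observed LogP-BUD association in the
        # same rows (predictions inherit the data's direction of effect)
        train, test = linear_partition(features, 0.8)
        model = fit("tree_ensemble_regression", train, seed=4)
        pred = predict_batch(model, test)
        rows = {c.parameter: c for c in correlation_screen(test, pred["bud_days"])}
        assert rows["logp"].r is not None
        observed_sign = np.sign(np.corrcoef(test["logp"], test["bud_days"])[0, 1])
        assert np.sign(rows["logp"].r) == observed_sign
        table = correlation_table(list(rows.values()))
        assert set(table.columns) == {"parameter", "r", "p", "significant"}
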