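"""Canonical discriminant fit, stepwise selection, scoring, LOO and the
published-function registry."""

import numpy as np
import pandas as pd
import pytest

from osteoinertia import discriminant as dd
from osteoinertia import reference_data as ref


def _two_group(rng, n=30, sep=(2.0, 0.0), sd=(1.0, 1.0)):
    p = len(sep)
    Xm = rng.normal(sep, sd, (n, p))
    Xf = rng.normal(0.0, sd, (n, p))
    cols = [f"v{i}" for i in range(p)]
    df = pd.DataFrame(np.vstack([Xm, Xf]), columns=cols)
    df["sex"] = ["male"] * n + ["female"] * n
    return df, cols


class TestFitDiscriminant:
    def test_balanced_centroids_symmetric(self):
        df, cols = _two_group(np.random.default_rng(0))
        fn = dd.fit_discriminant(df, cols)
        assert fn.centroid_male == pytest.approx(-fn.centroid_female, abs=1e-10)
        assert fn.sectioning_point == pytest.approx(0.0, abs=1e-10)

    def test_score_at_group_means_is_centroid(self):
        df, cols = _two_group(np.random.default_rng(1), sep=(1.5, -0.5))
        fn = dd.fit_discriminant(df, cols)
        means = df.groupby("sex")[cols].mean()
        assert fn.score(means.loc["male"]) == pytest.approx(fn.centroid_male, abs=1e-12)
        assert fn.score(means.loc["female"]) == pytest.approx(fn.centroid_female, abs=1e-12)

    def test_pooled_within_score_variance_is_one(self):
        df, cols = _two_group(np.random.default_rng(2), sep=(2.0, 1.0))
        fn = dd.fit_discriminant(df, cols)
        y = fn.score(df)
        ssw = sum(
            ((y[df["sex"] == s] - y[df["sex"] == s].mean()) ** 2).sum()
            for s in ("male", "female")
        )
        assert ssw / (len(df) - 2) == pytest.approx(1.0, abs=1e-10)

    def test_univariate_centroid_gap_recovers_separation(self):
        d = 1.7
        df, cols = _two_group(np.random.default_rng(3), n=10_000, sep=(d,), sd=(1.0,))
        fn = dd.fit_discriminant(df, cols)
        assert fn.centroid_male - fn.centroid_female == pytest.approx(d, rel=0.05)

    def test_wilks_lambda_in_unit_interval(self):
        df, cols = _two_group(np.random.default_rng(4))
        fn = dd.fit_discriminant(df, cols)
        assert 0 < fn.wilks_lambda < 1
        n, p, g = len(df), len(cols), 2
        expected_chi2 = -(n - 1 - (p + g) / 2) * np.log(fn.wilks_lambda)
        assert fn.chi_square == pytest.approx(expected_chi2)

    def test_collinear_variables_rejected(self):
        df, cols = _two_group(np.random.default_rng(5))
        df["dup"] = df["v0"]
        with pytest.raises(dd.SingularCovarianceError):
            dd.fit_discriminant(df, cols + ["dup"])

    def test_classification_invariant_to_sign_convention(self):
        df, cols = _two_group(np.random.default_rng(6))
        fn = dd.fit_discriminant(df, cols)
        flipped = dd.DiscriminantFunction(
            variables=fn.variables,
            coefficients=tuple(-c for c in fn.coefficients),
            constant=-fn.constant,
            centroid_male=-fn.centroid_male,
            centroid_female=-fn.centroid_female,
            sectioning_point=-fn.sectioning_point,
        )
        assert list(fn.classify(df)) == list(flipped.classify(df))


class TestStepwiseSelect:
    def test_informative_variable_found_among_noise(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            n = 30
            inf_col = np.r_[rng.normal(3.0, 1, n), rng.normal(0, 1, n)]
            df = pd.DataFrame(rng.normal(size=(2 * n, 4)),
                              columns=["n1", "n2", "n3", "n4"])
            df["signal"] = inf_col
            df["sex"] = ["male"] * n + ["female"] * n
            trace = dd.stepwise_select(df, ("n1", "n2", "n3", "n4", "signal"))
            hits += "signal" in trace.selected
        assert hits == 100

    def test_all_noise_mostly_empty(self):
        rng = np.random.default_rng(1)
        empties = 0
        trials = 100
        for _ in range(trials):
            df = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
            df["sex"] = ["male"] * 30 + ["female"] * 30
            empties += dd.stepwise_select(df, ("a", "b", "c")).empty
        # roughly 1 - family-wise type-I rate of the three F gates
        assert empties / trials > 0.75

    def test_duplicated_informative_variable_enters_once(self):
        rng = np.random.default_rng(2)
        n = 30
        base = np.r_[rng.normal(3.0, 1, n), rng.normal(0, 1, n)]
        df = pd.DataFrame({
            "a": base,
            "b": base + rng.normal(0, 1e-6, 2 * n),
            "sex": ["male"] * n + ["female"] * n,
        })
        trace = dd.stepwise_select(df, ("a", "b"))
        assert len(trace.selected) == 1

    def test_empty_result_is_not_an_error(self):
        df = pd.DataFrame({
            "a": [0.1, 0.2, 0.15, 0.12, 0.18, 0.11],
            "sex": ["male"] * 3 + ["female"] * 3,
        })
        trace = dd.stepwise_select(df, ("a",))
        assert isinstance(trace, dd.SelectionTrace)

    def test_invalid_gates_rejected(self):
        with pytest.raises(ValueError):
            dd.StepwiseConfig(f_enter=2.0, f_remove=3.0)


class TestScoringAndClassification:
    def test_published_left_function1_at_male_means(self):
        fn = dd.published_functions()[("left", 1)]
        y = fn.score({"density": 1.602, "Hn": 0.196, "sa_v": 0.256})
        assert y == pytest.approx(1.523, abs=1e-3)
        assert abs(y - fn.centroid_male) < 0.05

    def test_published_left_function4_at_male_mean(self):
        fn = dd.published_functions()[("left", 4)]
        y = fn.score({"sa_v": 0.377})
        assert y == pytest.approx(-1.519, abs=1e-3)
        assert abs(y - fn.centroid_male) < 0.05

    def test_all_zero_record_scores_constant(self):
        fn = dd.published_functions()[("right", 5)]
        assert fn.score({"sa_v": 0.0, "density": 0.0}) == fn.constant

    def test_missing_variable_named(self):
        fn = dd.published_functions()[("left", 1)]
        with pytest.raises(KeyError, match="Hn"):
            fn.score({"density": 1.6, "sa_v": 0.25})

    def test_tie_is_indeterminate(self):
        fn = dd.DiscriminantFunction(
            variables=("x",), coefficients=(1.0,), constant=0.0,
            centroid_male=1.0, centroid_female=-1.0, sectioning_point=0.0,
        )
        assert fn.classify({"x": 0.0}) == "indeterminate"
        assert fn.classify({"x": 0.5}) == "male"
        assert fn.classify({"x": -0.5}) == "female"

    def test_published_left_function3_on_group_means(self):
        fn = dd.published_functions()[("left", 3)]
        # male centroid is negative for this function: low SA:V reads male
        assert fn.classify({"sa_v": 0.386, "Hn": 0.198}) == "male"
        assert fn.classify({"sa_v": 0.450, "Hn": 0.192}) == "female"


class TestSectioningPoint:
    @pytest.mark.parametrize(
        "cm, cf, expected",
        [(1.554, -1.503, 0.026), (1.536, -1.589, -0.027), (2.0, -2.0, 0.0)],
    )
    def test_midpoint(self, cm, cf, expected):
        assert dd.sectioning_point(cm, cf) == pytest.approx(expected, abs=1e-3)

    def test_equal_centroids_rejected(self):
        with pytest.raises(ValueError):
            dd.sectioning_point(1.0, 1.0)

    def test_registry_sectioning_points_are_midpoints(self):
        for key, fn in dd.published_functions().items():
            mid = (fn.centroid_male + fn.centroid_female) / 2
            assert fn.sectioning_point == pytest.approx(mid, abs=1e-3), key


class TestRegistry:
    def test_left_function4_coefficients(self):
        fn = dd.published_functions()[("left", 4)]
        assert fn.variables == ("sa_v",)
        assert fn.coefficients == (50.593,)
        assert fn.constant == -20.593

    def test_right_function5_coefficients(self):
        fn = dd.published_functions()[("right", 5)]
        assert fn.variables == ("sa_v", "density")
        assert fn.coefficients == (55.060, -9.850)
        assert fn.constant == -4.021

    def test_registry_complete_and_consistent(self):
        reg = dd.published_functions()
        assert set(reg) == {(s, i) for s in ("left", "right") for i in range(1, 6)}
        for fn in reg.values():
            assert len(fn.variables) == len(fn.coefficients)
            assert 0 < fn.wilks_lambda < 1


class TestLooAccuracy:
    def test_perfect_separation(self):
        df = pd.DataFrame({
            "x": np.r_[np.linspace(10, 11, 10), np.linspace(0, 1, 10)],
            "sex": ["male"] * 10 + ["female"] * 10,
        })
        rep = dd.loo_accuracy(df, ("x",))
        assert rep.original.total_pct == 100.0
        assert rep.cross_validated.total_pct == 100.0

    def test_single_record_per_group_fails(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "sex": ["male", "female"]})
        with pytest.raises(Exception):
            dd.loo_accuracy(df, ("x",))

    def test_cross_validated_not_above_original_when_separable(self, left_mt3_cohort):
        rep = dd.loo_accuracy(left_mt3_cohort, ("sa_v", "Hn"))
        assert rep.cross_validated.total_pct <= rep.original.total_pct + 1e-9
        assert rep.cross_validated.total_pct >= 85.0


class TestSklearnEstimator:
    def test_fit_predict_roundtrip(self, left_mt3_cohort):
        clf = dd.SexDiscriminantClassifier(variables=("sa_v", "Hn"))
        X = left_mt3_cohort[["sa_v", "Hn"]]
        y = left_mt3_cohort["sex"].to_numpy()
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9
        assert clf.sectioning_point_ == pytest.approx(
            (clf.centroids_["male"] + clf.centroids_["female"]) / 2
        )

    def test_stepwise_estimator_selects(self, left_mt3_cohort):
        clf = dd.SexDiscriminantClassifier(
            variables=("Wn", "Hn", "pmi_z", "density", "sa_v"), stepwise=True
        )
        clf.fit(
            left_mt3_cohort[["Wn", "Hn", "pmi_z", "density", "sa_v"]],
            left_mt3_cohort["sex"].to_numpy(),
        )
        assert "sa_v" in clf.variables_
        assert not clf.selection_trace_.empty

    def test_get_set_params(self):
        clf = dd.SexDiscriminantClassifier()
        clf.set_params(f_enter=4.0)
        assert clf.get_params()["f_enter"] == 4.0

    def test_cross_val_score_integration(self, left_mt3_cohort):
        from sklearn.model_selection import cross_val_score

        X = left_mt3_cohort[["sa_v", "Hn"]].to_numpy()
        y = left_mt3_cohort["sex"].to_numpy()
        clf = dd.SexDiscriminantClassifier(variables=("sa_v", "Hn"))
        scores = cross_val_score(clf, X, y, cv=5)
        assert scores.mean() > 0.85
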