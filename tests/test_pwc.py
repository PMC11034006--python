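import numpy as np
import pytest

from pwcgen.errors import ConfigurationError, DegenerateDataError, LeakageError
from pwcgen.pwc import (
    ClassifierConfig,
    balanced_accuracy,
    cv_parcel_accuracy,
    fit_confound_model,
    fit_final_models,
    residualize,
    _fold_transform,
)
from pwcgen.pwc import test_across_sample as apply_across_sample
from tests.conftest import FAST_CLF, make_cohort


class TestConfoundModel:
    def test_exact_linear_feature_recovered(self):
        age = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
        x = (0.01 * age + 0.2)[:, None]
        m = fit_confound_model(x, age)
        assert m.slope[0] == pytest.approx(0.01, abs=1e-12)
        assert m.intercept[0] == pytest.approx(0.2, abs=1e-12)

    def test_orthogonal_feature_has_zero_slope(self):
        age = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) + 40.0
        # construct a feature exactly orthogonal to centered age
        x = np.array([1.0, -4.0, 6.0, -4.0, 1.0])[:, None]
        x = x - x.mean()
        x = x - (x[:, 0] @ (age - 40.0)) / ((age - 40.0) @ (age - 40.0)) * (
            age - 40.0
        )[:, None]
        m = fit_confound_model(x, age)
        assert abs(m.slope[0]) < 1e-10

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.standard_normal((50, 5))
        age = rng.uniform(20, 70, 50)
        m = fit_confound_model(x, age)
        design = np.column_stack([np.ones(50), age])
        beta = np.linalg.inv(design.T @ design) @ design.T @ x
        assert np.allclose(m.intercept, beta[0], atol=1e-10)
        assert np.allclose(m.slope, beta[1], atol=1e-10)

    def test_constant_age_rejected(self, rng):
        with pytest.raises(DegenerateDataError, match="age"):
            fit_confound_model(rng.standard_normal((10, 2)), np.full(10, 30.0))

    def test_residuals_uncorrelated_with_age_on_training_data(self, rng):
        x = rng.standard_normal((60, 8)) + np.outer(
            rng.uniform(20, 70, 60), rng.uniform(-0.02, 0.02, 8)
        )
        age = rng.uniform(20, 70, 60)
        m = fit_confound_model(x, age)
        resid = residualize(x, age, m)
        for j in range(8):
            assert abs(np.corrcoef(resid[:, j], age)[0, 1]) < 1e-8

    def test_zero_slope_model_subtracts_intercept_only(self, rng):
        x = rng.standard_normal((10, 3))
        from pwcgen.pwc import ConfoundModel

        m = ConfoundModel(intercept=np.array([1.0, 2.0, 3.0]), slope=np.zeros(3))
        out = residualize(x, np.full(10, 55.0), m)
        assert np.allclose(out, x - np.array([1.0, 2.0, 3.0]))

    def test_dimension_mismatch_rejected(self, rng):
        m = fit_confound_model(rng.standard_normal((10, 3)), rng.uniform(20, 60, 10))
        with pytest.raises(ConfigurationError, match="feature count"):
            residualize(rng.standard_normal((5, 4)), rng.uniform(20, 60, 5), m)

    def test_train_fitted_model_reduces_age_effect_in_test_data(self):
        # generator data with a known age slope: residualizing test features
        # with a train-fitted model shrinks the age correlation
        demo, conn, profiles, eff = make_cohort(
            n=200, delta=0.0, seed=8, age_range=(20.0, 80.0)
        )
        sig = eff.signal_parcels[0]
        x = profiles[:, sig, :]
        age = demo["age"].to_numpy()
        train, test = np.arange(0, 100), np.arange(100, 200)
        m = fit_confound_model(x[train], age[train])
        raw_r = np.abs(
            [np.corrcoef(x[test][:, j], age[test])[0, 1] for j in range(x.shape[1])]
        )
        res = residualize(x[test], age[test], m)
        new_r = np.abs(
            [np.corrcoef(res[:, j], age[test])[0, 1] for j in range(x.shape[1])]
        )
        assert new_r.mean() < raw_r.mean()


class TestBalancedAccuracy:
    def test_hand_computed_value(self):
        acc = balanced_accuracy(
            ["F", "F", "F", "M"], ["F", "F", "M", "M"]
        )
        assert acc == pytest.approx((2 / 3 + 1) / 2, abs=1e-12)

    def test_perfect_prediction(self):
        assert balanced_accuracy(["F", "M"], ["F", "M"]) == 1.0

    def test_majority_prediction_on_imbalance_is_chance(self):
        y = ["F"] * 9 + ["M"]
        assert balanced_accuracy(y, ["F"] * 10) == pytest.approx(0.5)

    def test_single_class_truth_rejected(self):
        with pytest.raises(DegenerateDataError):
            balanced_accuracy(["F", "F"], ["F", "M"])


class TestCvParcelAccuracy:
    def test_separable_feature_scores_one(self, rng):
        n = 40
        labels = np.array(["F", "M"] * (n // 2))
        x = np.where(labels == "F", 1.0, -1.0)[:, None]
        profiles = np.concatenate(
            [x[:, None, :], rng.standard_normal((n, 1, 1)) * 0.01], axis=2
        )
        ages = rng.uniform(20, 60, n)
        amap = cv_parcel_accuracy(profiles, labels, ages, FAST_CLF)
        assert amap.values[0] == pytest.approx(1.0)

    def test_permuted_labels_score_chance(self, rng):
        # permuting labels breaks the sex-feature link; the residual overlap
        # between permuted and true labels is chance-level, so the map mean
        # (averaged over permutations) sits at 0.5 within sampling error
        demo, conn, profiles, _ = make_cohort(n=200, n_parcels=10, seed=2)
        means = []
        for _ in range(3):
            labels = demo["sex"].to_numpy().copy()
            rng.shuffle(labels)
            amap = cv_parcel_accuracy(profiles, labels, demo["age"], FAST_CLF)
            means.append(amap.values.mean())
        assert abs(np.mean(means) - 0.5) <= 0.06

    def test_bit_identical_rerun_and_job_invariance(self):
        demo, conn, profiles, _ = make_cohort(n=60, n_parcels=6, signal=(1, 4), seed=3)
        a = cv_parcel_accuracy(profiles, demo["sex"], demo["age"], FAST_CLF)
        b = cv_parcel_accuracy(profiles, demo["sex"], demo["age"], FAST_CLF)
        c = cv_parcel_accuracy(
            profiles, demo["sex"], demo["age"], FAST_CLF, n_jobs=2
        )
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.values, c.values)

    def test_signal_parcels_outscore_background(self):
        demo, conn, profiles, eff = make_cohort(
            n=200, n_parcels=20, signal=(2, 7, 11, 16), delta=0.4, seed=4
        )
        amap = cv_parcel_accuracy(profiles, demo["sex"], demo["age"], FAST_CLF)
        sig = list(eff.signal_parcels)
        bg = [p for p in range(20) if p not in sig]
        assert amap.values[sig].mean() - amap.values[bg].mean() > 0.05

    def test_minority_class_smaller_than_folds_rejected(self, rng):
        labels = np.array(["F"] * 3 + ["M"] * 37)
        profiles = rng.standard_normal((40, 2, 4))
        with pytest.raises(DegenerateDataError, match="class"):
            cv_parcel_accuracy(profiles, labels, rng.uniform(20, 60, 40), FAST_CLF)


class TestFinalModelsAndAcrossSample:
    def _fitted(self, seed=0, n=80):
        demo, conn, profiles, eff = make_cohort(n=n, seed=seed)
        models = fit_final_models(
            profiles,
            demo["sex"],
            demo["age"],
            FAST_CLF,
            subject_ids=demo["subject_id"],
            sample_name="train",
        )
        return demo, profiles, models

    def test_kernel_restricted_to_rbf(self):
        _, _, models = self._fitted()
        assert all(m.params["kernel"] == "rbf" for m in models.models)

    def test_hyperparameter_selection_deterministic(self):
        _, _, m1 = self._fitted(seed=5)
        _, _, m2 = self._fitted(seed=5)
        assert [m.params for m in m1.models] == [m.params for m in m2.models]

    def test_leakage_guard_on_overlapping_subjects(self):
        demo, profiles, models = self._fitted()
        with pytest.raises(LeakageError):
            apply_across_sample(
                models,
                profiles,
                demo["sex"],
                demo["age"],
                test_subject_ids=demo["subject_id"],
            )

    def test_single_class_test_sample_rejected(self):
        demo, profiles, models = self._fitted()
        only_f = (demo["sex"] == "F").to_numpy()
        with pytest.raises(DegenerateDataError):
            apply_across_sample(
                models,
                profiles[only_f],
                demo["sex"][only_f],
                demo["age"][only_f],
                test_subject_ids=(),
            )

    def test_resubstitution_beats_cross_validation_on_average(self):
        gaps = []
        for seed in (0, 1, 2):
            demo, conn, profiles, _ = make_cohort(n=80, n_parcels=8, signal=(1, 5), seed=seed)
            cv = cv_parcel_accuracy(profiles, demo["sex"], demo["age"], FAST_CLF)
            models = fit_final_models(
                profiles, demo["sex"], demo["age"], FAST_CLF
            )
            resub = apply_across_sample(
                models,
                profiles,
                demo["sex"],
                demo["age"],
                allow_overlap=True,
            )
            gaps.append((resub.values - cv.values).mean())
        assert np.mean(gaps) >= 0

    def test_matched_site_generalizes_like_within_sample(self):
        # same site parameters for train and test: across-sample accuracy
        # tracks the within-CV accuracy map
        demo_a, _, prof_a, _ = make_cohort(n=400, n_parcels=10, signal=(1, 5, 9), seed=6)
        demo_b, _, prof_b, _ = make_cohort(n=400, n_parcels=10, signal=(1, 5, 9), seed=7)
        cv = cv_parcel_accuracy(prof_a, demo_a["sex"], demo_a["age"], FAST_CLF)
        models = fit_final_models(prof_a, demo_a["sex"], demo_a["age"], FAST_CLF)
        across = apply_across_sample(models, prof_b, demo_b["sex"], demo_b["age"])
        assert np.abs(across.values - cv.values).mean() < 0.05


class TestLeakageAudit:
    def test_fold_fits_ignore_held_out_rows(self, rng):
        x = rng.standard_normal((50, 6))
        ages = rng.uniform(20, 70, 50)
        train_idx = np.arange(0, 35)
        ref = _fold_transform(x, ages, train_idx)
        tampered = x.copy()
        tampered[35:] = 1e6  # poison the held-out rows
        tam_ages = ages.copy()
        tam_ages[35:] = -999.0
        out = _fold_transform(tampered, tam_ages, train_idx)
        assert np.array_equal(ref[0].intercept, out[0].intercept)
        assert np.array_equal(ref[0].slope, out[0].slope)
        assert np.array_equal(ref[1], out[1])
        assert np.array_equal(ref[2], out[2])

    def test_final_models_unchanged_by_test_data(self):
        demo, conn, profiles, _ = make_cohort(n=60, n_parcels=4, signal=(0, 2), seed=9)
        m1 = fit_final_models(profiles, demo["sex"], demo["age"], FAST_CLF)
        # "test data" never enters fit_final_models; refitting after looking
        # at arbitrary other data must give identical models
        demo2, _, profiles2, _ = make_cohort(n=60, n_parcels=4, signal=(0, 2), seed=10)
        _ = apply_across_sample(m1, profiles2, demo2["sex"], demo2["age"])
        m2 = fit_final_models(profiles, demo["sex"], demo["age"], FAST_CLF)
        for a, b in zip(m1.models, m2.models):
            assert a.params == b.params
            assert np.array_equal(a.confound.intercept, b.confound.intercept)
            assert np.array_equal(a.scaler_mean, b.scaler_mean)


class TestClassifierConfig:
    def test_grid_orders_linear_then_rbf(self):
        cfg = ClassifierConfig(
            kernels=("linear", "rbf"),
            C_grid=(1.0,),
            gamma_grid=("scale", 0.1),
            outer_folds=2,
            repeats=1,
            inner_folds=2,
        )
        grid = cfg.param_grid()
        assert grid[0] == {"kernel": "linear", "C": 1.0}
        assert {"kernel": "rbf", "C": 1.0, "gamma": 0.1} in grid

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassifierConfig(kernels=())
        with pytest.raises(ConfigurationError):
            ClassifierConfig(C_grid=(0.0,))
        with pytest.raises(ConfigurationError):
            ClassifierConfig(outer_folds=1)
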