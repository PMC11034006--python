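import numpy as np
import pytest
from scipy import stats as sps

from pwcgen import (
    DatasetSpec,
    EffectSpec,
    generate_cohort,
    generate_parcel_timeseries,
    make_multisite_study,
)
from pwcgen.connectome import (
    NuisanceSignals,
    clean_timeseries,
    compute_connectome,
    stack_profiles,
)
from pwcgen.errors import ConfigurationError
from pwcgen.pwc import cv_parcel_accuracy
from tests.conftest import FAST_CLF, make_cohort


def _spec(**kw):
    base = dict(name="a", n_subjects=40, age_range=(20.0, 50.0))
    base.update(kw)
    return DatasetSpec(**base)


class TestSpecValidation:
    def test_bad_site_scale_rejected(self):
        with pytest.raises(ConfigurationError, match="site_scale"):
            _spec(site_scale=0.0)

    def test_empty_age_range_rejected(self):
        with pytest.raises(ConfigurationError, match="age range"):
            _spec(age_range=(30.0, 30.0))

    def test_too_many_signal_parcels_rejected(self):
        with pytest.raises(ConfigurationError):
            EffectSpec(n_parcels=4, signal_parcels=(0, 1, 2, 3, 3))
        with pytest.raises(ConfigurationError):
            EffectSpec(n_parcels=3, signal_parcels=(0, 1, 5))


class TestGenerateCohort:
    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_connectomes_are_valid_correlation_matrices(self, seed):
        demo, conn, _, _ = make_cohort(n=30, seed=seed)
        assert np.array_equal(conn, conn.transpose(0, 2, 1))
        p = conn.shape[1]
        diag = conn[:, np.arange(p), np.arange(p)]
        assert (diag == 1.0).all()
        off = conn[:, ~np.eye(p, dtype=bool)]
        assert (off > -1.0).all() and (off < 1.0).all()

    def test_ages_within_range_and_sexes_balanced(self):
        demo, _, _, _ = make_cohort(n=100, age_range=(25.0, 35.0))
        assert demo["age"].between(25, 35).all()
        assert abs((demo["sex"] == "F").sum() - 50) <= 1
        assert demo["subject_id"].is_unique

    def test_bit_identical_under_same_seed(self):
        spec = _spec()
        eff = EffectSpec(8, (0, 4))
        d1, c1 = generate_cohort(spec, eff, 42)
        d2, c2 = generate_cohort(spec, eff, 42)
        assert d1.equals(d2)
        assert np.array_equal(c1, c2)

    def test_null_effect_gives_uniform_edge_pvalues(self):
        # delta = 0: every edge has the same distribution for both sexes,
        # so per-edge two-sample t p-values should be uniform.
        demo, conn, _, _ = make_cohort(
            n=160, n_parcels=35, signal=(0, 10, 20), delta=0.0, seed=5
        )
        is_f = (demo["sex"] == "F").to_numpy()
        iu = np.triu_indices(35, 1)
        edges = conn[:, iu[0], iu[1]]
        assert edges.shape[1] >= 500
        pvals = sps.ttest_ind(edges[is_f], edges[~is_f], axis=0).pvalue
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_cv_accuracy_monotone_in_sex_effect(self):
        # stronger delta must not reduce signal-parcel CV accuracy
        deltas = (0.0, 0.1, 0.2, 0.4)
        signal = (1, 5, 9)
        means = []
        for delta in deltas:
            accs = []
            for seed in (0, 1, 2):
                demo, conn, profiles, _ = make_cohort(
                    n=100, n_parcels=12, signal=signal, delta=delta, seed=seed
                )
                amap = cv_parcel_accuracy(
                    profiles[:, list(signal), :],
                    demo["sex"],
                    demo["age"],
                    FAST_CLF,
                )
                accs.append(amap.values.mean())
            means.append(np.mean(accs))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestGenerateParcelTimeseries:
    def test_identity_target_gives_near_zero_correlations(self):
        t = 2000
        p = 20
        ts, nuis = generate_parcel_timeseries(np.zeros((p, p)), t, seed=0)
        conn = compute_connectome(clean_timeseries(ts, nuis))
        iu = np.triu_indices(p, 1)
        frac_small = (np.abs(conn.matrix[iu]) < 4 / np.sqrt(t)).mean()
        assert frac_small >= 0.99

    def test_deterministic_small_case(self):
        z = np.array([[0.0, 0.3], [0.3, 0.0]])
        a1, n1 = generate_parcel_timeseries(z, 3, seed=9)
        a2, n2 = generate_parcel_timeseries(z, 3, seed=9)
        assert a1.values.shape == (3, 2)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(n1.values, n2.values)

    def test_unit_correlation_pair_recovered(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 20.0  # tanh(20) ~ 1: perfectly coupled pair
        ts, nuis = generate_parcel_timeseries(z, 500, seed=3)
        conn = compute_connectome(clean_timeseries(ts, nuis))
        assert conn.matrix[0, 1] > 0.999

    def test_recomputed_connectome_converges_to_target(self, rng):
        p = 15
        a = rng.normal(0, 0.15, (p, p))
        z = 0.25 + (a + a.T) / 2
        np.fill_diagonal(z, 0.0)
        target = np.tanh(z)
        np.fill_diagonal(target, 1.0)
        ts, nuis = generate_parcel_timeseries(z, 2000, seed=11)
        conn = compute_connectome(clean_timeseries(ts, nuis))
        iu = np.triu_indices(p, 1)
        assert np.abs(conn.matrix[iu] - target[iu]).mean() < 0.05

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ConfigurationError, match="T >= 3"):
            generate_parcel_timeseries(np.zeros((4, 4)), 2, seed=0)

    def test_indefinite_target_rejected_with_eigenvalue(self):
        r = np.array(
            [[1.0, 0.99, 0.99], [0.99, 1.0, -0.99], [0.99, -0.99, 1.0]]
        )
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        np.fill_diagonal(z, 0.0)
        with pytest.raises(ConfigurationError, match="eigenvalue"):
            generate_parcel_timeseries(z, 100, seed=0)


class TestMakeMultisiteStudy:
    def _specs(self):
        return [
            _spec(name="a"),
            _spec(name="b", site_offset=0.1),
            _spec(name="c", age_range=(30.0, 70.0)),
            _spec(name="d", noise_sd=0.6),
            _spec(name="e", unseen=True),
        ]

    def test_five_cohorts_and_rerun_identical(self):
        eff = EffectSpec(8, (0, 4))
        s1 = make_multisite_study(self._specs(), eff, 7)
        s2 = make_multisite_study(self._specs(), eff, 7)
        assert set(s1.cohorts) == {"a", "b", "c", "d", "e"}
        assert s1.unseen == "e"
        for name in s1.cohorts:
            assert np.array_equal(
                s1.cohorts[name].connectomes, s2.cohorts[name].connectomes
            )
            assert s1.cohorts[name].demographics.equals(
                s2.cohorts[name].demographics
            )

    def test_adding_a_dataset_does_not_perturb_others(self):
        eff = EffectSpec(8, (0, 4))
        specs = self._specs()
        small = make_multisite_study([specs[0], specs[1], specs[4]], eff, 3)
        big = make_multisite_study(specs, eff, 3)
        for name in ("a", "b", "e"):
            assert np.array_equal(
                small.cohorts[name].connectomes, big.cohorts[name].connectomes
            )

    def test_duplicate_names_rejected(self):
        eff = EffectSpec(8, (0, 4))
        specs = self._specs()
        specs[1] = _spec(name="a", site_offset=0.1)
        with pytest.raises(ConfigurationError, match="duplicate"):
            make_multisite_study(specs, eff, 0)

    def test_exactly_one_unseen_required(self):
        eff = EffectSpec(8, (0, 4))
        with pytest.raises(ConfigurationError, match="unseen"):
            make_multisite_study([_spec(name="a"), _spec(name="b")], eff, 0)

    def test_identical_site_params_give_exchangeable_sites(self):
        # no site differences: pooled per-edge means agree across cohorts
        eff = EffectSpec(10, (0, 5), sex_effect_size=0.0, age_slope=0.0)
        specs = [
            _spec(name=n, n_subjects=150, unseen=(n == "e"))
            for n in ("a", "b", "e")
        ]
        study = make_multisite_study(specs, eff, 21)
        iu = np.triu_indices(10, 1)
        ea = study.cohorts["a"].connectomes[:, iu[0], iu[1]]
        eb = study.cohorts["b"].connectomes[:, iu[0], iu[1]]
        t = sps.ttest_ind(ea.mean(axis=1), eb.mean(axis=1))
        assert t.pvalue > 0.001
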