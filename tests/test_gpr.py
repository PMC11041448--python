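"""GP synthesis: kernel, triplet formation, fitting, sampling, fold plan."""

import numpy as np
import pytest

from cevvo.cohort import ALL_CHANNELS, PatientRecord
from cevvo.gpr import (fit_triplet_gprs, form_triplets, rbf_kernel,
                       rbf_kernel_matrix, sample_synthetic_cohort,
                       split_synthetic_folds)
from cevvo.synthetic import CohortSpec, generate_cohort


def make_record(pid, outcome, run_hours, k=6, seed=0):
    """Minimal 8-channel record for counting/structure tests."""
    rng = np.random.default_rng(seed)
    times = np.linspace(1, run_hours * 3600.0, k)
    return PatientRecord(
        patient_id=pid, outcome=outcome, age=float(rng.uniform(30, 70)),
        sex=("female", "male")[int(rng.integers(2))],
        bmi=float(rng.uniform(20, 35)), cause="other", arrest_pre_ecmo=0,
        shock_pre_ecmo=0, reinfusion_site="right_ij", drainage_site="femoral",
        reinfusion_size=21.0, drainage_size=25.0,
        ventilation_type="volume_control", times=times,
        perfusion=rng.normal(size=(k, 8)), channels=ALL_CHANNELS)


def fake_cohort(n_success, n_fail):
    return ([make_record(f"s{i}", 1, 10 + i, seed=i)
             for i in range(n_success)]
            + [make_record(f"f{i}", 0, 10 + i, seed=100 + i)
               for i in range(n_fail)])


class TestRbfKernel:
    def test_closed_forms(self):
        x = np.array([1.0, 2.0])
        assert rbf_kernel(x, x, L=3.0) == pytest.approx(1.0)
        xi, xj = np.array([0.0]), np.array([2.0])  # d^2 = 4 = 2L for L=2
        assert rbf_kernel(xi, xj, L=2.0) == pytest.approx(np.exp(-1.0))

    def test_matches_direct_loop(self, rng):
        for _ in range(50):
            xi, xj = rng.normal(size=(2, 5))
            d2 = sum((a - b) ** 2 for a, b in zip(xi, xj))
            assert rbf_kernel(xi, xj, L=1.0) == pytest.approx(
                np.exp(-d2 / 2.0), rel=1e-12)
            assert rbf_kernel(xi, xj, L=1.0) == rbf_kernel(xj, xi, L=1.0)

    def test_denominator_is_2L_not_2L_squared(self):
        xi, xj = np.array([0.0]), np.array([4.0])  # d^2 = 16
        assert rbf_kernel(xi, xj, L=4.0) == pytest.approx(np.exp(-2.0))
        assert rbf_kernel(xi, xj, L=4.0, convention="squared") == \
            pytest.approx(np.exp(-0.5))

    @pytest.mark.parametrize("L", [0.0, -1.0])
    def test_nonpositive_length_scale_rejected(self, L):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], L=L)

    @pytest.mark.parametrize("L", [1.0, 100.0])
    def test_kernel_matrix_psd_after_jitter(self, rng, L):
        X = rng.normal(size=(40, 4))
        K = rbf_kernel_matrix(X, X, L)
        np.testing.assert_allclose(K, K.T, atol=1e-14)
        np.linalg.cholesky(K + 1e-8 * np.eye(40))  # must not raise


class TestTriplets:
    @pytest.mark.parametrize("n,expected,dropped", [
        (90, 30, 0), (24, 8, 0), (7, 2, 1),
    ])
    def test_group_counts(self, n, expected, dropped):
        records = fake_cohort(n, 0)
        if dropped:
            with pytest.warns(UserWarning, match="dropped"):
                triplets = form_triplets(records, grid_length=8)
        else:
            triplets = form_triplets(records, grid_length=8)
        assert len(triplets) == expected

    def test_members_share_outcome_and_sorted_by_run_time(self):
        triplets = form_triplets(fake_cohort(9, 6), grid_length=8)
        assert sum(t.outcome for t in triplets) == 3
        for t in triplets:
            runs = [r.run_seconds for r in t.member_records]
            assert runs == sorted(runs)

    def test_covariates_standardized_and_time_raw(self):
        triplets = form_triplets(fake_cohort(6, 3), grid_length=8)
        stacked = np.vstack([t.covariate_matrix for t in triplets])
        # time column is the raw grid index
        np.testing.assert_array_equal(np.unique(stacked[:, 3]), np.arange(8))
        t0 = triplets[0]
        assert t0.covariate_matrix.shape == (3 * 8, 4)
        assert t0.targets.shape == (3 * 8, 8)


class TestTripletGPR:
    def _one_gpr(self, L=1.0, grid=12):
        triplets = form_triplets(fake_cohort(3, 0), grid_length=grid)
        return fit_triplet_gprs(triplets[0], L=L)

    def _realistic_gpr(self, L, grid=24):
        spec = CohortSpec(n_success=3, n_fail=0, run_length_range=(4.0, 8.0),
                          seed=4)
        triplets = form_triplets(generate_cohort(spec), grid_length=grid)
        return fit_triplet_gprs(triplets[0], L=L)

    def test_exactly_eight_regressors(self):
        assert len(self._one_gpr().regressors) == 8

    def test_posterior_interpolates_training_targets(self):
        g = self._one_gpr(L=1.0)
        mean = g.posterior_mean(g.triplet.covariate_matrix)
        scale = np.std(g.triplet.targets, axis=0) + 1e-9
        err = np.abs(mean - g.triplet.targets) / scale
        assert err.max() < 0.05

    def test_long_length_scale_is_smoother(self):
        """Mean absolute first difference of samples shrinks from L=1 to L=100."""
        rough = {}
        for L in (1.0, 100.0):
            g = self._realistic_gpr(L=L)
            draws = g.sample(0, 20, np.random.default_rng(0))
            # compare on the device channels, per-channel scale-normalized
            scale = np.std(g.triplet.targets, axis=0) + 1e-9
            rough[L] = np.mean(np.abs(np.diff(draws, axis=1)) / scale)
        assert rough[100.0] < rough[1.0]

    def test_matches_sklearn_gp_posterior_mean(self):
        """Independent route: sklearn GP with length_scale sqrt(L) reproduces
        the posterior mean of the as-printed kernel exp(-d^2/(2L))."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF

        g = self._one_gpr(L=4.0, grid=10)
        X = g.triplet.covariate_matrix
        for v in (0, 3):
            y = g.triplet.targets[:, v]
            sk = GaussianProcessRegressor(
                kernel=RBF(length_scale=2.0), alpha=g.regressors[v].jitter,
                optimizer=None, normalize_y=False).fit(X, y)
            np.testing.assert_allclose(
                g.posterior_mean(X)[:, v], sk.predict(X), rtol=1e-6, atol=1e-6)


@pytest.fixture(scope="module")
def gprs():
    triplets = form_triplets(fake_cohort(90, 24), grid_length=8)
    return [fit_triplet_gprs(t, L=1.0) for t in triplets]


class TestSampling:
    def test_default_draw_counts_give_234(self, gprs):
        cohort = sample_synthetic_cohort(gprs, 3, 18,
                                         rng=np.random.default_rng(0))
        assert len(cohort) == 30 * 3 + 8 * 18 == 234
        assert sum(r.outcome for r in cohort) == 90

    def test_one_draw_per_triplet(self, gprs):
        cohort = sample_synthetic_cohort(gprs, 1, 1,
                                         rng=np.random.default_rng(0))
        assert len(cohort) == 38

    def test_reproducible_under_fixed_rng(self, gprs):
        a = sample_synthetic_cohort(gprs, 1, 2, rng=np.random.default_rng(3))
        b = sample_synthetic_cohort(gprs, 1, 2, rng=np.random.default_rng(3))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.perfusion, rb.perfusion)

    def test_labels_inherited_from_triplet(self, gprs):
        cohort = sample_synthetic_cohort(gprs, 2, 2,
                                         rng=np.random.default_rng(1))
        for rec in cohort:
            tid = rec.patient_id.rsplit("-", 1)[0]
            assert rec.outcome == (1 if tid.startswith("S") else 0)

    def test_invalid_draw_counts_rejected(self, gprs):
        with pytest.raises(ValueError):
            sample_synthetic_cohort(gprs, 0, 18)


class TestSyntheticFolds:
    def test_group_structure_and_exclusions(self):
        triplets = form_triplets(fake_cohort(90, 24), grid_length=8)
        plan = split_synthetic_folds(triplets, np.random.default_rng(0))
        assert len(plan.groups) == 5
        assert all(len(g) == 7 for g in plan.groups)
        assert len(plan.excluded) == 3  # 8 unsuccessful, 5 used
        used = [t for g in plan.groups for t in g]
        assert len(used) == len(set(used)) == 35

    def test_each_group_expands_to_36_patients(self):
        triplets = form_triplets(fake_cohort(90, 24), grid_length=8)
        plan = split_synthetic_folds(triplets, np.random.default_rng(0))
        gprs = {t.triplet_id: fit_triplet_gprs(t, 1.0) for t in triplets}
        cohort = sample_synthetic_cohort(list(gprs.values()), 3, 18,
                                         rng=np.random.default_rng(0))
        for pg in plan.patient_groups(cohort):
            assert len(pg) == 36

    def test_same_rng_same_plan(self):
        triplets = form_triplets(fake_cohort(90, 24), grid_length=8)
        a = split_synthetic_folds(triplets, np.random.default_rng(9))
        b = split_synthetic_folds(triplets, np.random.default_rng(9))
        assert a.groups == b.groups and a.excluded == b.excluded

    def test_insufficient_triplets_rejected(self):
        triplets = form_triplets(fake_cohort(9, 6), grid_length=8)
        with pytest.raises(ValueError):
            split_synthetic_folds(triplets, np.random.default_rng(0))


def test_end_to_end_gpr_on_generated_cohort():
    """Real generator -> triplets -> GPs -> synthetic cohort, on a tiny scale."""
    spec = CohortSpec(n_success=6, n_fail=3, run_length_range=(4.0, 8.0), seed=2)
    records = generate_cohort(spec)
    triplets = form_triplets(records, grid_length=16)
    assert len(triplets) == 3
    gprs = [fit_triplet_gprs(t, L=1.0) for t in triplets]
    cohort = sample_synthetic_cohort(gprs, 2, 2, rng=np.random.default_rng(0))
    assert len(cohort) == 6
    assert all(r.perfusion.shape == (16, 8) for r in cohort)
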