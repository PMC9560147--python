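import numpy as np
import pytest
from scipy import stats

from boundedplan import (SubjectSpec, generate_cohort, generate_subject)
from boundedplan.cohort import SubjectConditionBetas, noiseless_betas
from boundedplan.information import Hypothesis
from boundedplan.links import LINKS
from boundedplan.regression import (behavior_correlation, compare_group,
                                    design_matrix, fit_information_regression,
                                    grid_search_fit, loocv, nested_f_test)

H0, H1 = Hypothesis.H0_DELAYED, Hypothesis.H1_PROSPECTIVE


def make_betas(y, subject_id="s0", conditions=None):
    n = len(y)
    conditions = conditions or tuple(("x", i) for i in range(n))
    return SubjectConditionBetas(subject_id=subject_id, roi_label="roi",
                                 conditions=conditions,
                                 betas=np.asarray(y, float), error_rate=0.0)


@pytest.fixture(scope="module")
def prof_max(full_grid):
    return full_grid.get(H1, 500.0, 500.0)


class TestFit:
    @pytest.mark.parametrize("link", sorted(LINKS))
    def test_noiseless_recovery_is_exact_for_every_link(self, prof_max, link):
        a0, a1, a2 = 0.5, 1.0, 2.0
        X = design_matrix(prof_max, link)
        y = a0 + X @ [a1, a2]
        fit = fit_information_regression(make_betas(y), prof_max, link)
        assert fit.R2 == pytest.approx(1.0, abs=1e-12)
        assert fit.alpha0 == pytest.approx(a0, abs=1e-8)
        assert fit.alpha1 == pytest.approx(a1, abs=1e-8)
        assert fit.alpha2 == pytest.approx(a2, abs=1e-8)

    def test_negative_trend_pins_slope_at_zero(self, prof_max):
        y = 5.0 - 0.3 * prof_max.I2_by_condition  # decreasing in I2
        fit = fit_information_regression(make_betas(y), prof_max, "linear")
        assert fit.alpha2 == 0.0
        assert fit.alpha1 >= 0.0

    def test_constrained_matches_unconstrained_when_interior(self, prof_max):
        rng = np.random.default_rng(3)
        X = design_matrix(prof_max, "linear")
        y = 1.0 + X @ [0.8, 0.6] + rng.normal(0, 0.2, 12)
        fit = fit_information_regression(make_betas(y), prof_max)
        A = np.column_stack([np.ones(12), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if coef[1] > 0 and coef[2] > 0:  # interior solution
            assert fit.alpha1 == pytest.approx(coef[1], abs=1e-10)
            assert fit.alpha2 == pytest.approx(coef[2], abs=1e-10)

    def test_slope_estimates_are_unbiased(self, prof_max):
        rng = np.random.default_rng(11)
        X = design_matrix(prof_max, "linear")
        a1s, a2s = [], []
        for _ in range(200):
            y = 0.2 + X @ [1.0, 0.5] + rng.normal(0, 0.5, 12)
            f = fit_information_regression(make_betas(y), prof_max)
            a1s.append(f.alpha1)
            a2s.append(f.alpha2)
        assert np.mean(a1s) == pytest.approx(1.0, abs=3 * np.std(a1s)
                                             / np.sqrt(200))
        assert np.mean(a2s) == pytest.approx(0.5, abs=3 * np.std(a2s)
                                             / np.sqrt(200))

    def test_constant_column_is_pinned_with_warning(self, prof_max):
        import copy
        prof = copy.deepcopy(prof_max)
        prof.I1_by_condition = np.full(12, 2.0)
        y = np.arange(12.0)
        with pytest.warns(RuntimeWarning, match="constant"):
            fit = fit_information_regression(make_betas(y), prof, "linear")
        assert fit.alpha1 == 0.0


class TestNestedF:
    def test_identical_rss_gives_f_zero_p_one(self, prof_max):
        # residual constructed orthogonal to the full design: adding I2
        # cannot reduce the RSS, so F = 0 and p = 1 exactly
        X = design_matrix(prof_max, "linear")
        A = np.column_stack([np.ones(12), X])
        rng = np.random.default_rng(1)
        r = rng.normal(size=12)
        r -= A @ np.linalg.lstsq(A, r, rcond=None)[0]
        y = 0.5 + 2.0 * X[:, 0] + r
        F, p = nested_f_test(make_betas(y), prof_max)
        assert F == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_exact_fit_flags_p_zero(self, prof_max):
        X = design_matrix(prof_max, "linear")
        y = 1.0 + X @ [1.0, 1.0]
        F, p = nested_f_test(make_betas(y), prof_max)
        assert np.isinf(F) and p == 0.0

    def test_null_p_values_are_uniform(self, prof_max):
        rng = np.random.default_rng(2024)
        X = design_matrix(prof_max, "linear")
        ps = []
        for _ in range(1000):
            y = 0.3 + 0.7 * X[:, 0] + rng.normal(0, 1.0, 12)  # alpha2 = 0
            ps.append(nested_f_test(make_betas(y), prof_max)[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_strong_planning_signal(self, prof_max):
        rng = np.random.default_rng(7)
        X = design_matrix(prof_max, "linear")
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            y = 0.3 + X @ [0.5, 1.0] + rng.normal(0, 1.0, 12)
            rejections += nested_f_test(make_betas(y), prof_max)[1] < 0.05
        assert rejections / n_sim >= 0.95


class TestGridSearch:
    def test_noiseless_argmax_at_generating_point(self, full_grid):
        sp = SubjectSpec(subject_id="s0", hypothesis=H1, beta1=20.0,
                         beta2=20.0, alpha0=0.0, alpha1=1.0, alpha2=1.0,
                         noise_sd=0.0, seed=0)
        rec = generate_subject(sp, full_grid)
        res = grid_search_fit(rec, full_grid, H1, "linear")
        assert res.best.R2 == pytest.approx(1.0, abs=1e-12)
        assert (res.best.beta1, res.best.beta2) == (20.0, 20.0)

    def test_noiseless_h1_data_prefers_h1(self, full_grid):
        sp = SubjectSpec(subject_id="s0", hypothesis=H1, beta1=20.0,
                         beta2=20.0, alpha1=1.0, alpha2=1.0, noise_sd=0.0,
                         seed=0)
        rec = generate_subject(sp, full_grid)
        r1 = grid_search_fit(rec, full_grid, H1)
        r0 = grid_search_fit(rec, full_grid, H0)
        assert r1.best.R2 == pytest.approx(1.0, abs=1e-12)
        assert r0.best.R2 < r1.best.R2

    def test_h0_and_h1_profiles_not_collinear(self, prof_max, full_grid):
        p0 = full_grid.get(H0, 500.0, 500.0)
        D = np.column_stack([np.ones(12), p0.I1_by_condition,
                             p0.I2_by_condition,
                             prof_max.I2_by_condition])
        assert np.linalg.matrix_rank(D, tol=1e-8) == 4

    def test_bounded_best_at_least_as_good_as_reference(self, full_grid):
        rng = np.random.default_rng(5)
        prof = full_grid.get(H1, 20.0, 20.0)
        y = 0.1 + prof.I1_by_condition + rng.normal(0, 1.0, 12)
        res = grid_search_fit(make_betas(y), full_grid, H1)
        assert res.not_bounded is not None
        assert res.best.R2 >= res.not_bounded.R2 - 1e-12


class TestLoocv:
    def test_noiseless_correctly_specified_loocv_is_zero(self, prof_max):
        X = design_matrix(prof_max, "linear")
        y = 0.2 + X @ [1.0, 0.7]
        assert loocv(make_betas(y), prof_max) == pytest.approx(0.0,
                                                               abs=1e-12)

    def test_h1_data_crossvalidates_better_under_h1(self, full_grid):
        prof1 = full_grid.get(H1, 20.0, 20.0)
        prof0 = full_grid.get(H0, 20.0, 20.0)
        rng = np.random.default_rng(0)
        sd = 0.25 * np.std(prof1.I1_by_condition + prof1.I2_by_condition)
        wins = 0
        n = 40
        for i in range(n):
            y = (prof1.I1_by_condition + prof1.I2_by_condition
                 + rng.normal(0, sd, 12))
            b = make_betas(y)
            wins += loocv(b, prof1) < loocv(b, prof0)
        assert wins / n >= 0.9

    def test_loocv_increases_with_noise(self, prof_max):
        rng = np.random.default_rng(9)
        X = design_matrix(prof_max, "linear")
        mean = 0.2 + X @ [1.0, 0.7]
        levels = np.linspace(0.05, 2.0, 20)
        mses = []
        for sd in levels:
            vals = [loocv(make_betas(mean + rng.normal(0, sd, 12)), prof_max)
                    for _ in range(10)]
            mses.append(np.mean(vals))
        rho = stats.spearmanr(levels, mses).statistic
        assert rho > 0


class TestGroupComparison:
    def _fits(self, values, ids=None):
        from boundedplan.regression import RegressionFit
        ids = ids or [f"s{i}" for i in range(len(values))]
        return [RegressionFit(subject_id=i, hypothesis=H1, beta1=1, beta2=1,
                              link="linear", alpha0=0, alpha1=0, alpha2=0,
                              R2=v, RSS=0.0) for i, v in zip(ids, values)]

    def test_identical_samples_give_null_result(self):
        a = self._fits([0.5, 0.6, 0.7, 0.8])
        comp = compare_group(a, a, method="permutation_one_sided")
        assert comp.p_value == pytest.approx(1.0, abs=0.01)
        assert comp.statistic_value == 0.0

    def test_unpaired_subjects_rejected(self):
        a = self._fits([0.5, 0.6], ids=["a", "b"])
        b = self._fits([0.5, 0.6], ids=["a", "c"])
        with pytest.raises(ValueError, match="unpaired"):
            compare_group(a, b)

    def test_bonferroni_threshold_recorded(self):
        a = self._fits([0.5, 0.6, 0.7])
        b = self._fits([0.4, 0.5, 0.6])
        comp = compare_group(a, b, bonferroni_divisor=17)
        assert comp.correction == "bonferroni"
        assert comp.corrected_alpha == pytest.approx(0.05 / 17, abs=1e-12)
        assert comp.corrected_alpha == pytest.approx(0.00294, abs=1e-5)

    def test_permutation_is_seeded(self):
        a = self._fits([0.5, 0.62, 0.71, 0.8, 0.55])
        b = self._fits([0.45, 0.6, 0.68, 0.77, 0.5])
        p1 = compare_group(a, b, method="permutation_one_sided", seed=4)
        p2 = compare_group(a, b, method="permutation_one_sided", seed=4)
        assert p1.p_value == p2.p_value

    def test_h1_cohorts_yield_significant_h1_advantage(self, full_grid):
        # cohorts generated under prospective planning: the paired R2
        # comparison should be significant at alpha = 0.001 essentially
        # always at this signal-to-noise level
        prof = full_grid.get(H1, 20.0, 20.0)
        sd = 0.25 * np.std(prof.I1_by_condition + prof.I2_by_condition)
        n_cohorts, hits = 20, 0
        for c in range(n_cohorts):
            specs = [SubjectSpec(subject_id=f"s{i}", hypothesis=H1,
                                 beta1=20.0, beta2=20.0, alpha1=1.0,
                                 alpha2=1.0, noise_sd=sd,
                                 seed=1000 * c + i)
                     for i in range(19)]
            records, _ = generate_cohort(specs, full_grid)
            f1 = [grid_search_fit(r, full_grid, H1).best for r in records]
            f0 = [grid_search_fit(r, full_grid, H0).best for r in records]
            comp = compare_group(f1, f0, method="paired_rmANOVA")
            hits += (comp.p_value < 0.001
                     and comp.effect_direction == "A>B")
        assert hits / n_cohorts >= 0.95


class TestBehaviorCorrelation:
    def test_exact_linear_relation(self):
        eu = np.linspace(0.7, 0.99, 10)
        err = 1.0 - (0.2 + 0.8 * eu)
        bc = behavior_correlation(eu, err)
        assert bc.correlation == pytest.approx(1.0, abs=1e-12)
        assert bc.slope == pytest.approx(0.8, abs=1e-12)

    def test_binomial_cohorts_show_positive_slope(self, full_grid):
        prof = full_grid.get(H1, 20.0, 20.0)
        rng = np.random.default_rng(21)
        sig = 0
        n_cohorts = 200
        for _ in range(n_cohorts):
            eu = rng.uniform(0.75, 1.0, 19)
            err = rng.binomial(120, 1 - eu) / 120
            if np.ptp(err) == 0:
                continue
            bc = behavior_correlation(eu, err)
            sig += bc.p_value < 0.05 and bc.slope > 0
        assert sig / n_cohorts > 0.5

    def test_shuffle_false_positive_rate_matches_alpha(self):
        rng = np.random.default_rng(100)
        fractions = []
        n_shuffles = 1000
        for draw in range(5):
            eu = rng.normal(0.9, 0.05, 19)
            err = rng.normal(0.1, 0.05, 19)  # independent of eu
            bc = behavior_correlation(eu, err, n_shuffles=n_shuffles,
                                      seed=draw)
            fractions.append(bc.shuffle_significant_fraction)
        overall = np.mean(fractions)
        se = np.sqrt(0.05 * 0.95 / (5 * n_shuffles))
        assert overall == pytest.approx(0.05, abs=2 * se + 0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            behavior_correlation([0.9] * 5, [0.1, 0.2, 0.1, 0.2, 0.1])
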