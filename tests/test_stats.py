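"""t-tests, reliability, normalization, and estimation-accuracy statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from beautyvar import (EstimationRecord, NumberSet, estimation_accuracy,
                       normalize_ratings, number_set_stats, paired_t_one_sided,
                       pearson, quartet_actuals, two_sample_t_one_sided)
from beautyvar.stats import test_retest as retest_reliability
from beautyvar.reference import (disputed_means, disputed_sds,
                                 undisputed_means, undisputed_sds)

from conftest import make_table


class TestTwoSample:
    def test_reference_quartet_sd_contrast(self):
        # published per-image SDs: high-variance (2.1,2.1,2.2,2.0) vs
        # low-variance (1.3,1.5,1.4,1.6)
        res = two_sample_t_one_sided(disputed_sds(), undisputed_sds(), "greater")
        assert res.df == 6
        assert res.statistic == pytest.approx(8.51, abs=0.005)
        assert res.cohens_d == pytest.approx(6.02, abs=0.005)
        assert res.p_value < 0.001

    def test_reference_quartet_mean_contrast(self):
        res = two_sample_t_one_sided(disputed_means(), undisputed_means(), "greater")
        assert res.statistic == pytest.approx(-1.18, abs=0.005)
        assert res.cohens_d == pytest.approx(0.83, abs=0.005)
        assert res.p_value == pytest.approx(0.86, abs=0.005)

    def test_identical_groups(self):
        res = two_sample_t_one_sided([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.cohens_d == 0.0

    def test_degenerate_zero_variance(self):
        res = two_sample_t_one_sided([4, 4], [3, 3], "greater")
        assert res.statistic == math.inf and res.p_value == 0.0
        res = two_sample_t_one_sided([3, 3], [4, 4], "greater")
        assert res.statistic == -math.inf and res.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_matches_scipy_pooled_t(self, alternative):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        res = two_sample_t_one_sided(a, b, alternative)
        ref = sps.ttest_ind(a, b, equal_var=True, alternative=alternative)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_cohens_d_t_identity(self):
        # d = |t| * sqrt(1/n_a + 1/n_b) for the pooled test
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
            res = two_sample_t_one_sided(a, b)
            assert res.cohens_d == pytest.approx(
                abs(res.statistic) * math.sqrt(1 / 6 + 1 / 9))

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_one_sided([1], [1, 2])


class TestPaired:
    def test_equal_pairs_give_zero(self):
        res = paired_t_one_sided([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0 and res.df == 3

    def test_constant_shift_is_degenerate(self):
        res = paired_t_one_sided([1, 2, 3, 4], [0, 1, 2, 3], "greater")
        assert res.statistic == math.inf

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.3, 1, 12)
        res = paired_t_one_sided(a, b, "greater")
        ref = sps.ttest_rel(a, b, alternative="greater")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_rejection_rate_matches_nominal_power(self):
        # Monte-Carlo vs the noncentral-t closed form
        rng = np.random.default_rng(3)
        n, shift, reps, alpha = 20, 0.5, 2000, 0.05
        t_crit = sps.t.ppf(1 - alpha, n - 1)
        power = 1 - sps.nct.cdf(t_crit, n - 1, shift * math.sqrt(n))
        rejections = 0
        for _ in range(reps):
            diffs = rng.normal(shift, 1.0, n)
            res = paired_t_one_sided(diffs, np.zeros(n), "greater")
            rejections += res.p_value < alpha
        assert rejections / reps == pytest.approx(power, abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_one_sided([1, 2], [1, 2, 3])


class TestPearson:
    @given(a=hst.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=hst.floats(-10, 10))
    @settings(max_examples=30, deadline=None)
    def test_scale_shift_invariance(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 3.0, 7.0, 6.0])
        base = pearson(x, y).r
        scaled = pearson(a * x + b, y).r
        assert scaled == pytest.approx(math.copysign(base, a * base), abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestRetest:
    def test_duplicated_session_is_perfectly_reliable(self):
        rows = []
        for p, base in zip("xyz", (2, 4, 6)):
            for img in "ab":
                rows += [(f"p{p}", img, 1, base), (f"p{p}", img, 2, base)]
        res = retest_reliability(make_table(rows))
        assert res.r == pytest.approx(1.0)

    def test_scale_reversal_is_perfectly_antireliable(self):
        rows = []
        for p, base in zip("xyz", (2, 4, 6)):
            for img in "ab":
                rows += [(f"p{p}", img, 1, base), (f"p{p}", img, 2, 8 - base)]
        assert retest_reliability(make_table(rows)).r == pytest.approx(-1.0)

    def test_high_rho_simulation_recovers_attenuated_r(self, sim_config):
        import dataclasses

        from beautyvar import simulate_ratings
        cfg = dataclasses.replace(sim_config, n_participants=500,
                                  test_retest_rho=0.9)
        res = retest_reliability(simulate_ratings(cfg))
        # discretization attenuates the latent rho slightly
        assert 0.80 <= res.r <= 0.95

    def test_too_few_participants(self):
        rows = [("p1", "a", 1, 4), ("p1", "a", 2, 4),
                ("p2", "a", 1, 5), ("p2", "a", 2, 5)]
        with pytest.raises(ValueError, match="participant"):
            retest_reliability(make_table(rows))


class TestNormalization:
    def test_subtracts_participant_mean(self):
        t = make_table([("p1", img, 1, b)
                        for img, b in zip("abcd", (2, 4, 4, 6))])
        norm = normalize_ratings(t, list("abcd"))
        assert list(norm.loc["p1"]) == [-2.0, 0.0, 0.0, 2.0]

    def test_rows_sum_to_zero(self, sim_table):
        quartet = [f"disputed_{i}" for i in range(1, 5)]
        norm = normalize_ratings(sim_table, quartet)
        np.testing.assert_allclose(norm.sum(axis=1), 0.0, atol=1e-12)

    def test_constant_ratings_normalize_to_zero(self):
        t = make_table([("p1", img, 1, 4) for img in "abcd"])
        assert (normalize_ratings(t, list("abcd")).loc["p1"] == 0).all()

    def test_participant_level_shift_leaves_group_sd_unchanged(self):
        rows = [("p1", img, 1, b) for img, b in zip("abcd", (2, 4, 4, 6))]
        rows += [("p2", img, 1, b) for img, b in zip("abcd", (1, 3, 5, 7))]
        shifted = [("p1", img, 1, b + 1) for img, b in zip("abcd", (2, 4, 4, 6))]
        shifted += [("p2", img, 1, b) for img, b in zip("abcd", (1, 3, 5, 7))]
        sd_a = normalize_ratings(make_table(rows), list("abcd")).std(ddof=1)
        sd_b = normalize_ratings(make_table(shifted), list("abcd")).std(ddof=1)
        np.testing.assert_allclose(sd_a, sd_b)


class TestActuals:
    def test_worked_example_triplet(self):
        # mean of 1, 3, 5 is 3; dispersion (sample SD) is 2 — applied to a
        # three-image set for the instructions' arithmetic
        t = make_table([("p1", img, 1, b) for img, b in zip("abc", (1, 3, 5))])
        mat = t.ratings_matrix(images=list("abc"))
        assert mat.loc["p1"].mean() == 3.0
        assert mat.loc["p1"].std(ddof=1) == 2.0

    def test_quartet_actuals(self):
        t = make_table([("p1", img, 1, b) for img, b in zip("abcd", (1, 7, 1, 7))])
        row = quartet_actuals(t, list("abcd")).loc["p1"]
        assert row.actual_mean == 4.0
        assert row.actual_sd == pytest.approx(math.sqrt(12.0))  # 3.464

    def test_constant_quartet(self):
        t = make_table([("p1", img, 1, 4) for img in "abcd"])
        row = quartet_actuals(t, list("abcd")).loc["p1"]
        assert row.actual_mean == 4.0 and row.actual_sd == 0.0


def _rec(pid, est_mean, est_sd=1.0, act_mean=4.0, act_sd=1.5):
    return EstimationRecord(pid, "quartet", "q1", est_mean, est_sd,
                            act_mean, act_sd)


class TestEstimationAccuracy:
    def test_outlier_threshold_is_inclusive(self):
        recs = [_rec(f"p{i}", 3.0 + i * 0.1, act_mean=3.0 + i * 0.1)
                for i in range(5)] + [_rec("px", 18.0)]
        res = estimation_accuracy(recs, "mean")
        assert res.n_excluded == 1
        assert res.correlation.n == 5

    def test_perfect_estimates_give_r_one(self):
        recs = [_rec(f"p{i}", 2.0 + i, act_mean=2.0 + i) for i in range(4)]
        assert estimation_accuracy(recs, "mean").correlation.r == pytest.approx(1.0)

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError):
            estimation_accuracy([_rec("p1", 20.0), _rec("p2", 19.0),
                                 _rec("p3", 18.0)], "mean")

    def test_sd_fidelity_recovered_from_simulation(self):
        import dataclasses

        from beautyvar import (default_archetypes, simulate_estimations,
                               simulate_ratings)
        from beautyvar.simulate import SimulationConfig
        cfg = SimulationConfig(n_participants=1000,
                               archetypes=default_archetypes(4, 0, 0),
                               estimation_sd_fidelity=0.18,
                               two_sessions=False, seed=8)
        table = simulate_ratings(cfg)
        recs = simulate_estimations(
            table, {"q": [f"disputed_{i}" for i in range(1, 5)]}, [], cfg)
        res = estimation_accuracy(recs, "sd")
        assert res.correlation.r == pytest.approx(0.18, abs=0.07)


class TestNumberSets:
    def test_worked_example_and_degenerates(self):
        sets = [NumberSet("a", (1, 3, 5)), NumberSet("b", (4, 4)),
                NumberSet("c", (1, 7))]
        rep = number_set_stats(sets)
        actual = rep.actuals.set_index("set_id")
        assert actual.loc["a", "mean"] == 3.0 and actual.loc["a", "sd"] == 2.0
        assert actual.loc["b", "sd"] == 0.0
        assert actual.loc["c", "sd"] == pytest.approx(math.sqrt(18.0))  # 4.243

    def test_singleton_sd_missing(self):
        rep = number_set_stats([NumberSet("solo", (4.0,))])
        assert math.isnan(rep.actuals.loc[0, "sd"])

    def test_accuracy_stratified_by_size(self):
        sets = [NumberSet(f"s2_{i}", (1.0 + i, 5.0)) for i in range(4)]
        sets += [NumberSet(f"s4_{i}", (1.0 + i, 2.0, 5.0, 6.0)) for i in range(4)]
        recs = [EstimationRecord("p1", "number_set", s.set_id,
                                 s.mean, s.sd, s.mean, s.sd) for s in sets]
        rep = number_set_stats(sets, recs)
        assert set(rep.accuracy_by_size) == {2, 4}
        for size in (2, 4):
            assert rep.accuracy_by_size[size]["mean"].r == pytest.approx(1.0)
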