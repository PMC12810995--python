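"""Feasibility statistics: success rates, Wilson/t intervals, gamma fits."""

import numpy as np
import pytest
from scipy import stats

from needletrack.evaluation import (FrameResult, GammaFit, TrackingResult,
                                    error_heatmap, gamma_moment_fit,
                                    one_sample_t_test, success_rate,
                                    summarize_experiment,
                                    t_confidence_interval, wilson_interval)


class TestSuccessRate:
    def test_all_zero_errors(self):
        assert success_rate([0.0] * 10) == 1.0

    def test_error_exactly_at_threshold_is_failure(self):
        assert success_rate([5.0]) == 0.0
        assert success_rate([4.999999]) == 1.0

    def test_half_success(self):
        assert success_rate([4.0, 6.0]) == 0.5

    def test_excluded_frames_left_out_of_both_sides(self):
        assert success_rate([1.0, 9.0, 9.0, 2.0], excluded={1, 2}) == 1.0

    def test_order_invariance(self, rng):
        errs = rng.uniform(0, 10, size=50)
        assert success_rate(errs) == success_rate(errs[::-1])

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            success_rate([1.0, 2.0], excluded={0, 1})

    def test_infinite_error_counts_as_failure(self):
        assert success_rate([np.inf, 1.0]) == 0.5


class TestWilsonInterval:
    def wilson_oracle(self, k, n, conf=0.95):
        """Closed-form Wilson bounds written out independently."""
        z = stats.norm.ppf(0.5 + conf / 2)
        p = k / n
        a = (p + z * z / (2 * n)) / (1 + z * z / n)
        b = (z / (1 + z * z / n)) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
        return a - b, a + b

    def test_ten_of_ten(self):
        wi = wilson_interval(10, 10)
        assert wi.lo == pytest.approx(0.7225, abs=5e-5)
        assert wi.hi == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (50, 60), (599, 600)])
    def test_matches_closed_form_oracle(self, k, n):
        wi = wilson_interval(k, n)
        lo, hi = self.wilson_oracle(k, n)
        assert wi.lo == pytest.approx(max(lo, 0.0), abs=1e-12)
        assert wi.hi == pytest.approx(min(hi, 1.0), abs=1e-12)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(1, 12), (7, 9), (30, 31)]:
            lo, hi = statsmodels.proportion_confint(k, n, method="wilson")
            wi = wilson_interval(k, n)
            assert wi.lo == pytest.approx(lo, abs=1e-10)
            assert wi.hi == pytest.approx(hi, abs=1e-10)

    def test_zero_successes_lower_bound_zero(self):
        assert wilson_interval(0, 17).lo == 0.0

    def test_mirror_symmetry(self):
        for k, n in [(2, 9), (5, 11), (0, 4)]:
            assert wilson_interval(k, n).lo == pytest.approx(
                1 - wilson_interval(n - k, n).hi, abs=1e-12)

    def test_contains_point_estimate_and_narrows_with_n(self):
        for k, n in [(3, 10), (30, 100), (300, 1000)]:
            wi = wilson_interval(k, n)
            assert wi.lo <= k / n <= wi.hi
        widths = [wilson_interval(3 * m, 10 * m).hi - wilson_interval(3 * m, 10 * m).lo
                  for m in (1, 10, 100)]
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 4)


class TestTStatistics:
    def test_segmentation_validation_interval(self):
        # mean 1.55 mm, sd 1.01 mm, n = 201 -> (1.41, 1.69) to 2 decimals
        lo, hi = t_confidence_interval(1.55, 1.01, 201)
        assert round(lo, 2) == 1.41
        assert round(hi, 2) == 1.69

    def test_zero_sd_degenerates_to_point(self):
        assert t_confidence_interval(2.0, 0.0, 10) == (2.0, 2.0)

    def test_large_n_approaches_normal_interval(self):
        lo, hi = t_confidence_interval(0.0, 1.0, 10 ** 6)
        z = stats.norm.ppf(0.975)
        assert hi == pytest.approx(z / 1000.0, abs=1e-4 / 1000)
        assert lo == pytest.approx(-hi)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            t_confidence_interval(1.0, 1.0, 1)

    def test_t_test_all_at_threshold(self):
        res = one_sample_t_test([5.0, 5.0, 5.0])
        assert res.statistic == 0.0 and res.p_value == 0.5
        assert not res.significant

    def test_t_test_far_below_threshold(self, rng):
        x = rng.normal(1.0, 0.1, size=100)
        res = one_sample_t_test(x, mu0=5.0)
        # closed-form check of the statistic
        t_ref = (x.mean() - 5.0) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert res.statistic == pytest.approx(t_ref, rel=1e-10)
        assert res.p_value < 1e-10
        assert res.significant

    def test_t_test_mirror_symmetry(self, rng):
        x = rng.normal(4.0, 1.0, size=30)
        p_less = one_sample_t_test(x, mu0=5.0).p_value
        mirrored = 10.0 - x  # reflect about mu0
        p_mirror = one_sample_t_test(mirrored, mu0=5.0).p_value
        assert p_less == pytest.approx(1.0 - p_mirror, abs=1e-12)

    def test_zero_variance_flagged_with_sign(self):
        res = one_sample_t_test([1.0, 1.0, 1.0], mu0=5.0)
        assert res.zero_variance and res.mean_offset_sign == -1
        assert res.p_value == 0.0 and res.significant


class TestGammaFit:
    def test_analytic_scale_from_mean_and_shape(self):
        fit = GammaFit.from_mean_and_shape(1.55, 7.64)
        assert round(fit.theta, 2) == 0.20

    def test_exponential_closed_form(self):
        # skewness 2 and mean 1 define the unit exponential: alpha=theta=1
        fit = GammaFit.from_mean_and_shape(1.0, 4.0 / 2.0 ** 2)
        assert fit.alpha == pytest.approx(1.0) and fit.theta == pytest.approx(1.0)

    def test_moment_identities_hold_by_construction(self, rng):
        x = rng.gamma(3.0, 2.0, size=500)
        fit = gamma_moment_fit(x)
        assert fit.alpha == pytest.approx(4.0 / fit.sample_skewness ** 2, rel=1e-12)
        assert fit.theta == pytest.approx(fit.sample_mean / fit.alpha, rel=1e-12)

    def test_parameter_recovery_on_large_sample(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(7.64, 0.20, size=100_000)
        fit = gamma_moment_fit(x)
        assert abs(fit.alpha - 7.64) / 7.64 < 0.10
        assert abs(fit.theta - 0.20) / 0.20 < 0.10

    def test_uses_bias_corrected_skewness(self, rng):
        x = rng.gamma(2.0, 1.0, size=50)
        fit = gamma_moment_fit(x)
        g = stats.skew(x, bias=False)
        assert fit.sample_skewness == pytest.approx(g, rel=1e-12)

    def test_non_positive_skew_rejected(self):
        with pytest.raises(ValueError):
            gamma_moment_fit([1.0, 2.0, 3.0, 4.0, 5.0])  # symmetric, skew 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GammaFit(alpha=-1, theta=1, sample_mean=1, sample_skewness=1)


def _result(sample_id, R, errors, excluded=(), method="zero_filled"):
    frames = [FrameResult(i, e, (i not in excluded) and e < 5.0, i in excluded)
              for i, e in enumerate(errors)]
    return TrackingResult(sample_id, R, method, frames, n_klines=int(256 // R),
                          move_window=(2, 5))


class TestSummarize:
    def test_single_sample_all_success(self):
        df = summarize_experiment([_result("a", 8, [1.0] * 10)])
        row = df.iloc[0]
        assert row.mean_success_rate == 1.0 and row.sd_success_rate == 0.0
        assert row.n_klines == 32

    def test_two_sample_mean_and_sample_sd(self):
        res = [_result("a", 8, [1.0, 9.0]),     # rate 0.5
               _result("b", 8, [1.0, 1.0])]     # rate 1.0
        row = summarize_experiment(res).iloc[0]
        assert row.mean_success_rate == pytest.approx(0.75)
        assert row.sd_success_rate == pytest.approx(0.35355, abs=1e-4)

    def test_one_row_per_R_and_method(self):
        res = [_result("a", R, [1.0], method=m)
               for R in (8, 12) for m in ("zero_filled", "crnn")]
        df = summarize_experiment(res)
        assert len(df) == 4
        assert set(df.method) == {"zero_filled", "crnn"}

    def test_pooled_wilson_excludes_excluded_frames(self):
        res = [_result("a", 8, [1.0] * 8 + [9.0] * 2, excluded={8, 9})]
        row = summarize_experiment(res).iloc[0]
        wi = wilson_interval(8, 8)
        assert row.wilson_lo == pytest.approx(wi.lo)


class TestHeatmap:
    def test_excluded_tail_blanked_and_deterministic(self, tmp_path):
        # one sample with its final 12 frames excluded, one fully scored
        errors = list(np.linspace(0.5, 6.5, 60))
        res = [_result("I", 16, errors, excluded=set(range(48, 60))),
               _result("II", 16, errors)]
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        error_heatmap(res, p1)
        error_heatmap(res, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.stat().st_size > 0

    def test_requires_results(self, tmp_path):
        with pytest.raises(ValueError):
            error_heatmap([], tmp_path / "x.png")
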