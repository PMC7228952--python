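"""Bias-correction algebra and agreement statistics."""

import numpy as np
import pytest
from scipy import stats

from axodense.calibration import (
    CorrectionModel,
    CountRecord,
    LinearBiasCorrector,
    apply_correction,
    bland_altman,
    cov_stats,
    evaluate,
    fit_correction,
    success_rate,
)


def records_from(mc, ac, counters=1):
    out = []
    for i, (m, a) in enumerate(zip(mc, ac)):
        manual = np.full(counters, m, dtype=float) if np.isscalar(m) else np.asarray(m)
        out.append(CountRecord(image_id=f"img{i}", manual_counts=manual, ac=float(a)))
    return out


class TestCorrection:
    def test_noiseless_linear_bias_recovered(self, rng):
        mc = rng.uniform(10, 90, 50)
        recs = records_from(mc, 0.8 * mc + 5)
        model = fit_correction(recs)
        assert model.a == pytest.approx(0.8, abs=1e-9)
        assert model.b == pytest.approx(5.0, abs=1e-9)
        assert model.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_identity_relationship(self, rng):
        mc = rng.uniform(10, 90, 20)
        model = fit_correction(records_from(mc, mc))
        assert model.a == pytest.approx(1.0, abs=1e-9)
        assert model.b == pytest.approx(0.0, abs=1e-7)

    def test_correction_inverts_noiseless_bias_to_machine_precision(self, rng):
        mc = rng.uniform(10, 90, 30)
        ac = 0.8 * mc + 5
        model = fit_correction(records_from(mc, ac))
        assert np.allclose(apply_correction(model, ac), mc, atol=1e-9)

    def test_rat_validation_coefficients_evaluate_exactly(self):
        # published rat validation fit: AC = 0.801*MC + 4.8
        model = CorrectionModel(a=0.801, b=4.8)
        assert apply_correction(model, 52.9) == pytest.approx((52.9 - 4.8) / 0.801)
        assert apply_correction(model, 52.9) == pytest.approx(60.05, abs=5e-3)

    def test_ols_slope_within_sampling_error(self, rng):
        n = 300
        mc = rng.uniform(10, 90, n)
        ac = 0.8 * mc + 5 + rng.normal(0, 1, n)
        model = fit_correction(records_from(mc, ac))
        se = 1.0 / np.sqrt(((mc - mc.mean()) ** 2).sum())
        assert abs(model.a - 0.8) < 3 * se

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            CorrectionModel(a=0.0, b=1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_correction(records_from([5, 5, 5, 5], [1, 2, 3, 4]))

    def test_sklearn_interface_round_trip(self, rng):
        mc = rng.uniform(10, 90, 40)
        ac = 1.2 * mc - 3
        est = LinearBiasCorrector().fit(mc, ac)
        assert est.get_params() == {}
        assert np.allclose(est.correct(ac), mc, atol=1e-9)


class TestBlandAltman:
    def test_zero_errors_give_zero_limits(self):
        recs = records_from([10, 20, 30], [10, 20, 30])
        bias, (lo, hi) = bland_altman(recs)
        assert bias == 0 and lo == 0 and hi == 0

    def test_normal_errors_converge_to_1p96_sigma(self, rng):
        sigma = 5.0
        n = 1000
        mc = rng.uniform(30, 60, n)
        recs = records_from(mc, np.maximum(0.0, mc + rng.normal(0, sigma, n)))
        bias, (lo, hi) = bland_altman(recs)
        # sampling error of the SD is ~sigma/sqrt(2n)
        tol = 3 * 1.96 * sigma / np.sqrt(2 * n)
        assert hi - bias == pytest.approx(1.96 * sigma, abs=3 * tol)
        assert bias == pytest.approx(0.0, abs=3 * sigma / np.sqrt(n))

    def test_order_invariance(self, rng):
        mc = rng.uniform(10, 90, 30)
        recs = records_from(mc, mc + rng.normal(0, 2, 30))
        ba, (lo_a, hi_a) = bland_altman(recs)
        bb, (lo_b, hi_b) = bland_altman(list(reversed(recs)))
        assert ba == pytest.approx(bb, abs=1e-12)
        assert (lo_a, hi_a) == pytest.approx((lo_b, hi_b), abs=1e-12)


class TestSuccessRate:
    def test_exact_predictions_always_succeed(self, rng):
        manual = rng.uniform(30, 60, (20, 4))
        recs = [
            CountRecord(image_id=str(i), manual_counts=m, ac=float(m.mean()),
                        ac_corrected=float(m.mean()))
            for i, m in enumerate(manual)
        ]
        assert success_rate(recs) == 1.0

    def test_distant_predictions_never_succeed(self, rng):
        manual = rng.uniform(30, 60, (20, 4))
        recs = [
            CountRecord(image_id=str(i), manual_counts=m, ac=1000.0, ac_corrected=1000.0)
            for i, m in enumerate(manual)
        ]
        assert success_rate(recs) == 0.0

    def test_wrong_counter_number_excluded_with_warning(self, rng):
        good = CountRecord("a", rng.uniform(30, 60, 4), ac=45.0, ac_corrected=45.0)
        bad = CountRecord("b", rng.uniform(30, 60, 3), ac=45.0, ac_corrected=45.0)
        with pytest.warns(UserWarning):
            assert success_rate([good, bad]) == success_rate([good])

    def test_fifth_counter_coverage_matches_t_interval_theory(self, rng):
        # A count drawn from the same distribution as the 4 counters falls
        # inside the t-based CI of their mean with probability
        # P(|T_3| <= t_crit / (sqrt(4) * sqrt(1 + 1/4))): the CI targets the
        # mean, not a new observation, so coverage is well below 95%.
        n = 4000
        manual = rng.normal(50, 5, (n, 4))
        fifth = rng.normal(50, 5, n)
        recs = [
            CountRecord(image_id=str(i), manual_counts=m, ac=max(0.0, f),
                        ac_corrected=float(f))
            for i, (m, f) in enumerate(zip(manual, fifth))
        ]
        rate = success_rate(recs)
        tcrit = stats.t.ppf(0.975, df=3)
        expected = 2 * stats.t.cdf(tcrit / (np.sqrt(4) * np.sqrt(1 + 1 / 4)), df=3) - 1
        assert rate == pytest.approx(expected, abs=0.03)


class TestCoV:
    def test_identical_counters_give_zero(self):
        recs = records_from([10, 20], [10, 20], counters=4)
        assert cov_stats(recs) == 0.0

    def test_hand_computed_example(self):
        rec = CountRecord("a", np.array([48.0, 52.0]), ac=50.0)
        expected = np.std([48, 52], ddof=1) / 50.0
        assert cov_stats([rec]) == pytest.approx(expected)
        assert cov_stats([rec]) == pytest.approx(0.0566, abs=1e-4)

    def test_zero_mean_images_excluded(self):
        zero = CountRecord("z", np.array([0.0, 0.0]), ac=0.0)
        other = CountRecord("a", np.array([48.0, 52.0]), ac=50.0)
        assert cov_stats([zero, other]) == cov_stats([other])


class TestEvaluate:
    def test_corrected_mae_beats_uncorrected_under_linear_bias(self, rng):
        mc = rng.uniform(20, 80, 200)
        ac = 0.8 * mc + 10 + rng.normal(0, 1, 200)  # >= 10% systematic bias
        recs = records_from(mc, np.maximum(ac, 0), counters=4)
        mae_raw = np.mean([abs(r.ac - r.mc_mean) for r in recs])
        report = evaluate(recs, fit_correction(recs))
        assert report.mae <= mae_raw
        assert report.r2 > 0.9
        assert report.loa[0] <= report.loa[1]
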