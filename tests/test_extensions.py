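"""Phenology days, maximum growth rate, the QCH and deviation statistics."""

import numpy as np
import pytest

import dendrofit as df
from dendrofit.cascade import CascadeConfig, FitResult, fit_cascade
from dendrofit.extensions import (
    deviations,
    fit_qch,
    growth_quantile_day,
    max_growth,
    phenology_metrics,
    residual_synchrony,
)
from dendrofit.growth import LG5Params, lg5_derivative, lg5_predict
from dendrofit.season_bounds import BoundsEstimate, estimate_ab


def _fake_fit(params):
    return FitResult(method="Nelder-Mead", weighted=False, params=params,
                     nll=0.0, objective=0.0, converged=True)


def _bounds_near_asymptotes(p, margin=1e-6):
    from dendrofit.growth import lg5_inverse
    a = p.L + margin * (p.K - p.L)
    b = p.K - margin * (p.K - p.L)
    t = lg5_inverse(p, [a, b])
    return BoundsEstimate(a=a, b=b, t_a=float(t[0]), t_b=float(t[1]), nll_at_opt=0.0)


class TestGrowthQuantileDay:
    P = LG5Params(19.0, 19.46, 170, 0.06, 1.0)  # symmetric

    def test_midpoint_is_inflection_day(self):
        b = _bounds_near_asymptotes(self.P)
        assert growth_quantile_day(_fake_fit(self.P), b, 0.5) == pytest.approx(170.0, abs=1e-3)

    def test_strictly_increasing_in_q(self):
        p = LG5Params(19.0, 19.46, 170, 0.06, 2.3)
        b = _bounds_near_asymptotes(p, margin=1e-3)
        days = [growth_quantile_day(_fake_fit(p), b, q) for q in (0.1, 0.25, 0.5, 0.75, 0.9)]
        assert np.all(np.diff(days) > 0)

    def test_rejects_targets_outside_asymptotes(self):
        b = BoundsEstimate(a=18.5, b=19.4, t_a=100.0, t_b=250.0, nll_at_opt=0.0)
        with pytest.raises(ValueError, match="lower asymptote"):
            growth_quantile_day(_fake_fit(self.P), b, 0.01)

    def test_rejects_q_outside_unit_interval(self):
        b = _bounds_near_asymptotes(self.P)
        with pytest.raises(ValueError):
            growth_quantile_day(_fake_fit(self.P), b, 1.5)


class TestMaxGrowth:
    def test_symmetric_logistic_closed_form(self):
        p = LG5Params(19.0, 19.46, 170.4, 0.06, 1.0)
        rate, day = max_growth(_fake_fit(p))
        # integer-day grid sits 0.4 days off the true peak, hence the slack
        assert rate == pytest.approx(0.06 * 0.46 / 4, rel=1e-3)
        assert day == 170

    def test_reference_best_model_rate(self, reference_params):
        # the reference best-model parameters give 0.01 cm/day at two decimals
        rate, _ = max_growth(_fake_fit(reference_params))
        assert round(rate, 2) == 0.01

    def test_integer_argmax_near_analytic_inflection(self):
        for theta in (0.3, 1.0, 3.7):
            p = LG5Params(19.0, 19.46, 201.6, 0.06, theta)
            _, day = max_growth(_fake_fit(p))
            assert abs(day - p.doy_ip) <= 1.0


class TestQCH:
    def test_identical_residuals_reproduce_base(self, noiseless_series, noiseless_fit):
        # noiseless data: every residual is ~0, selection degenerates to all
        # in-season points and the hull is the base fit
        s = noiseless_series
        best = noiseless_fit.best
        est = estimate_ab(s.doy, s.dbh, best)
        qch = fit_qch(s.doy, s.dbh, best, est)
        np.testing.assert_allclose(
            lg5_predict(qch.params, s.doy), lg5_predict(best.params, s.doy), atol=1e-3
        )

    def test_hull_sits_above_base_mid_season(self, noisy_series, noisy_fit):
        s = noisy_series
        best = noisy_fit.best
        est = estimate_ab(s.doy, s.dbh, best)
        qch = fit_qch(s.doy, s.dbh, best, est)
        days = np.linspace(est.t_a, est.t_b, 100)
        above = lg5_predict(qch.params, days) >= lg5_predict(best.params, days) - 1e-6
        assert above.mean() >= 0.9

    def test_pause_deviations_mostly_negative(self):
        spec = df.SimSpec(noise_sd=0.003, pauses=[df.Pause(165, 30, 0.5)], seed=11)
        s = df.simulate_tree(spec)
        best = fit_cascade(s.doy, s.dbh, CascadeConfig(seed=0)).best
        est = estimate_ab(s.doy, s.dbh, best)
        qch = fit_qch(s.doy, s.dbh, best, est)
        dev = deviations(s.doy, s.dbh, qch)
        assert np.mean(dev.raw_dev <= 0.002) >= 0.8

    def test_selected_points_are_top_residuals(self, noisy_series, noisy_fit):
        s = noisy_series
        best = noisy_fit.best
        est = estimate_ab(s.doy, s.dbh, best)
        qch = fit_qch(s.doy, s.dbh, best, est, q=0.8)
        resid = s.dbh - lg5_predict(best.params, s.doy)
        assert len(qch.selected) >= 5
        in_season = (s.doy >= est.t_a) & (s.doy <= est.t_b)
        assert np.min(resid[qch.selected]) >= np.median(resid[in_season]) - 1e-12


class TestDeviations:
    def test_observations_on_hull_give_zero_index(self):
        p = LG5Params(19.0, 19.46, 170, 0.06, 1.5)
        doy = np.arange(110.0, 300.0, 7.0)
        qch = df.QCHResult(params=p, selected=np.arange(5), q=0.8, nll=0.0)
        dev = deviations(doy, lg5_predict(p, doy), qch)
        np.testing.assert_allclose(dev.raw_dev, 0.0, atol=1e-12)
        assert dev.annual_index == 0.0

    def test_hand_computed_three_points(self):
        p = LG5Params(19.0, 19.46, 170, 0.06, 1.5)
        doy = np.array([150.0, 170.0, 250.0])
        dbh = lg5_predict(p, doy) + np.array([-0.01, -0.02, 0.005])
        qch = df.QCHResult(params=p, selected=np.arange(3), q=0.8, nll=0.0)
        dev = deviations(doy, dbh, qch)
        slopes = lg5_derivative(p, doy)
        np.testing.assert_allclose(dev.raw_dev, [-0.01, -0.02, 0.005], atol=1e-12)
        np.testing.assert_allclose(dev.weighted_dev, np.array([-0.01, -0.02, 0.005]) * slopes)
        assert dev.annual_index == pytest.approx(np.sum(dev.weighted_dev))

    def test_mid_season_deviation_weighs_more(self):
        # the same raw deficit counts more when expected growth is fast
        p = LG5Params(19.0, 19.46, 170, 0.06, 1.5)
        doy = np.array([170.0, 290.0])
        dbh = lg5_predict(p, doy) - 0.01
        qch = df.QCHResult(params=p, selected=np.arange(2), q=0.8, nll=0.0)
        dev = deviations(doy, dbh, qch)
        assert abs(dev.weighted_dev[0]) > abs(dev.weighted_dev[1])

    def test_index_invariant_to_constant_shift(self):
        p = LG5Params(19.0, 19.46, 170, 0.06, 1.5)
        p_shift = LG5Params(19.5, 19.96, 170, 0.06, 1.5)
        doy = np.arange(110.0, 300.0, 7.0)
        dbh = lg5_predict(p, doy) - 0.005
        d0 = deviations(doy, dbh, df.QCHResult(p, np.arange(3), 0.8, 0.0))
        d1 = deviations(doy, dbh + 0.5, df.QCHResult(p_shift, np.arange(3), 0.8, 0.0))
        assert d1.annual_index == pytest.approx(d0.annual_index, abs=1e-12)


class TestSynchrony:
    def _stand_with_truth_fits(self, pauses, n=6, seed=21):
        template = df.SimSpec(noise_sd=0.003, pauses=pauses, seed=seed)
        series, specs = df.simulate_stand(n, template, shared_pauses=True, seed=seed)
        return [(s.doy, s.dbh, _fake_fit(sp.truth)) for s, sp in zip(series, specs)]

    def test_identical_residual_series_have_zero_se(self):
        p = LG5Params(19.0, 19.46, 170, 0.06, 1.5)
        doy = np.arange(110.0, 300.0, 7.0)
        dbh = lg5_predict(p, doy) + 0.01
        table = residual_synchrony([(doy, dbh, _fake_fit(p))] * 3)
        np.testing.assert_allclose(table["two_se"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["mean_resid"], 0.01, atol=1e-12)

    def test_single_tree_rejected(self):
        p = LG5Params(19.0, 19.46, 170, 0.06, 1.5)
        doy = np.arange(110.0, 300.0, 7.0)
        with pytest.raises(ValueError):
            residual_synchrony([(doy, lg5_predict(p, doy), _fake_fit(p))])

    def test_shared_pause_dips_below_two_se(self):
        # residuals against each tree's own truth: the synchronized pause
        # shows as a stand-wide mean dip beyond 2 SE
        table = residual_synchrony(self._stand_with_truth_fits([df.Pause(160, 40, 0.6)]))
        window = table[(table["doy"] >= 170) & (table["doy"] <= 210)]
        assert np.any(window["mean_resid"] < -window["two_se"] * 1.0)
        assert window["mean_resid"].min() < -0.005

    def test_no_pause_stays_flat(self):
        table = residual_synchrony(self._stand_with_truth_fits([]))
        assert np.all(np.abs(table["mean_resid"]) < 0.01)
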