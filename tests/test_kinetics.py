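"""Rate fitting: decay normalization, window selection, OLS recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipasym import (
    HydrolysisTimeCourse,
    KineticsError,
    NormalizationRecord,
    RateFit,
    ScenarioSpec,
    TABLE_BILAYERS,
    delta_x,
    estimate_plateau,
    fit_rate,
    normalize_rate,
    rate_ratio,
    select_initial_window,
    simulate_timecourse,
)
from lipasym.kinetics import read_timecourse_csv


def _make_tc(times, pe):
    pe = np.asarray(pe, dtype=float)
    frame = pd.DataFrame({"POPE": pe, "rest": 1.0 - pe})
    return HydrolysisTimeCourse(times_s=np.asarray(times, float), fractions=frame)


class TestTimeCourseValidation:
    def test_closure_enforced(self):
        frame = pd.DataFrame({"POPE": [0.3, 0.2, 0.1, 0.05], "rest": [0.7] * 4})
        with pytest.raises(KineticsError, match="closure"):
            HydrolysisTimeCourse(times_s=np.arange(4.0), fractions=frame)

    def test_times_strictly_increasing(self):
        with pytest.raises(KineticsError, match="increasing"):
            _make_tc([0.0, 1.0, 1.0, 2.0], [0.3, 0.2, 0.1, 0.05])

    def test_minimum_points(self):
        with pytest.raises(KineticsError, match=">= 4"):
            _make_tc([0.0, 1.0, 2.0], [0.3, 0.2, 0.1])


class TestDeltaX:
    def test_identity_at_x0(self):
        dx = delta_x([0.35], x0=0.35, x_inf=0.05)
        assert dx[0] == pytest.approx(1.0)
        assert np.log(dx[0]) == pytest.approx(0.0)

    def test_midpoint_value(self):
        assert delta_x([0.20], 0.35, 0.05)[0] == pytest.approx(0.5)

    def test_plateau_maps_to_zero(self):
        dx = delta_x([0.35, 0.05], 0.35, 0.05)
        assert dx[1] == pytest.approx(0.0)
        assert not (dx[1] > 0)  # excluded from any log fit

    def test_inverted_bounds_error(self):
        with pytest.raises(KineticsError, match="exceed"):
            delta_x([0.2], x0=0.05, x_inf=0.35)

    def test_all_below_plateau_error(self):
        with pytest.raises(KineticsError, match="below the plateau"):
            delta_x([0.04, 0.03], 0.35, 0.05)


class TestEstimatePlateau:
    def test_trailing_mean(self):
        series = [0.3, 0.2, 0.1, 0.051, 0.049, 0.050]
        assert estimate_plateau(series) == pytest.approx(0.05)

    def test_constant_series(self):
        assert estimate_plateau([0.2] * 5) == pytest.approx(0.2)

    def test_override_verbatim(self):
        assert estimate_plateau([0.3, 0.2, 0.1], override=0.123) == 0.123

    def test_too_short(self):
        with pytest.raises(KineticsError, match="short"):
            estimate_plateau([0.3, 0.2], m=3)


class TestWindowSelection:
    def test_perfectly_linear_full_window(self):
        t = np.arange(10.0)
        assert select_initial_window(t, -0.1 * t) == (0, 10)

    def test_two_regime_matches_exhaustive_prefix_oracle(self):
        # exactly linear for the first 7 points, then flat
        t = np.arange(12.0)
        y = np.where(t <= 6, -0.1 * t, -0.6)
        # oracle: largest prefix (>= 4 points) with OLS R^2 >= 0.98
        expected = max(
            stop
            for stop in range(4, 13)
            if stats.linregress(t[:stop], y[:stop]).rvalue ** 2 >= 0.98
        )
        assert select_initial_window(t, y) == (0, expected)
        assert expected == 8  # frozen from the oracle

    def test_too_few_points(self):
        with pytest.raises(KineticsError, match="4"):
            select_initial_window(np.arange(3.0), np.zeros(3))

    def test_no_linear_regime(self):
        t = np.arange(6.0)
        y = np.array([0.0, -1.0, 0.5, -2.0, 1.0, -3.0])
        with pytest.raises(KineticsError, match="no linear initial regime"):
            select_initial_window(t, y, r2_threshold=0.999)


class TestFitRate:
    @pytest.mark.parametrize("k_true", [1e-4, 1e-3, 1e-2, 1e-1, 1.0])
    def test_noiseless_recovery_machine_precision(self, k_true):
        spec = ScenarioSpec(
            bilayer=TABLE_BILAYERS["PE/PG"], k_true=k_true, noise_sigma=0.0
        )
        fit = fit_rate(simulate_timecourse(spec), x_inf=spec.x_inf)
        assert fit.k == pytest.approx(k_true, rel=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert not fit.negative_rate

    def test_zero_decay_gives_zero_rate(self):
        spec = ScenarioSpec(
            bilayer=TABLE_BILAYERS["PE/PG"], k_true=0.0, noise_sigma=0.0
        )
        fit = fit_rate(simulate_timecourse(spec), x_inf=None)
        assert fit.k == 0.0
        assert fit.zero_decay

    def test_matches_closed_form_regression(self, noiseless_timecourse):
        spec, tc = noiseless_timecourse
        fit = fit_rate(tc, x_inf=spec.x_inf)
        dx = delta_x(tc.series(), fit.x0, fit.x_inf)
        keep = dx > 0
        t, y = tc.times_s[keep], np.log(dx[keep])
        t, y = t[: fit.window[1]], y[: fit.window[1]]
        # closed-form OLS slope
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert fit.k == pytest.approx(-slope)

    def test_negative_rate_flagged_not_rejected(self):
        t = np.arange(6.0)
        pe = 0.2 + 0.01 * t  # rising "POPE": negative fitted rate
        tc = _make_tc(t, pe)
        fit = fit_rate(tc, x0=0.3, x_inf=0.1)
        assert fit.negative_rate and fit.k < 0

    def test_window_protects_against_late_slowdown(self):
        # two-regime curve: initial k = 0.01 /s, then 10x slower
        from lipasym import Slowdown

        spec = ScenarioSpec(
            bilayer=TABLE_BILAYERS["PE/PG"],
            k_true=0.01,
            noise_sigma=0.0,
            slowdown=Slowdown(onset=1.5, residual_factor=0.1),
        )
        tc = simulate_timecourse(spec)
        fit = fit_rate(tc, x_inf=spec.x_inf)
        assert abs(fit.k / spec.k_true - 1) < 0.10
        # the unwindowed full-series fit is badly biased
        dx = delta_x(tc.series(), tc.series()[0], spec.x_inf)
        keep = dx > 0
        res = stats.linregress(tc.times_s[keep], np.log(dx[keep]))
        assert abs(-res.slope / spec.k_true - 1) > 0.20

    def test_recovery_under_multiplicative_closure_noise(self):
        # abbreviated version of the 200-replicate study (full run in the
        # acceptance suite): median relative error well under 5%
        rng = np.random.default_rng(11)
        errs = []
        for k_true in np.logspace(-3, -1, 40):
            spec = ScenarioSpec(
                bilayer=TABLE_BILAYERS["PE/PG"],
                k_true=float(k_true),
                noise_sigma=0.01,
                seed=int(rng.integers(2**31)),
            )
            fit = fit_rate(simulate_timecourse(spec), x_inf=spec.x_inf)
            errs.append(abs(fit.k / k_true - 1))
        assert np.median(errs) < 0.05


class TestNormalization:
    def _fit(self, k=0.02, err=0.001):
        return RateFit(
            k=k, stderr_k=err, window=(0, 6), r_squared=0.99,
            x0=0.35, x_inf=0.05, n_points_used=6,
        )

    def test_identity_reference(self):
        norm = NormalizationRecord(1.0, 1.0, 1.0, 1.0)
        assert normalize_rate(self._fit(), norm).k == pytest.approx(0.02)

    def test_double_lipid_halves_rate(self):
        norm = NormalizationRecord(2.0, 1.0, 1.0, 1.0)
        assert normalize_rate(self._fit(), norm).k == pytest.approx(0.01)

    def test_half_protein_doubles_rate(self):
        norm = NormalizationRecord(1.0, 0.5, 1.0, 1.0)
        assert normalize_rate(self._fit(), norm).k == pytest.approx(0.04)

    def test_nonpositive_entries_rejected(self):
        with pytest.raises(KineticsError, match="positive"):
            NormalizationRecord(0.0, 1.0)


class TestRateRatio:
    def _fit(self, k, err=0.0):
        return RateFit(
            k=k, stderr_k=err, window=(0, 6), r_squared=0.99,
            x0=0.35, x_inf=0.05, n_points_used=6,
        )

    def test_equal_rates_give_unity(self):
        f = self._fit(0.01, 0.002)
        r, _ = rate_ratio(f, f)
        assert r == 1.0

    def test_thirty_five_fold(self):
        r, err = rate_ratio(self._fit(0.035), self._fit(0.001))
        assert r == pytest.approx(35.0)
        assert err == 0.0

    def test_delta_method_propagation(self):
        r, err = rate_ratio(self._fit(0.03, 0.003), self._fit(0.01, 0.002))
        assert r == pytest.approx(3.0)
        assert err == pytest.approx(3.0 * np.hypot(0.1, 0.2))

    def test_nonpositive_sym_rate_rejected(self):
        with pytest.raises(KineticsError, match="ratio undefined"):
            rate_ratio(self._fit(0.03), self._fit(0.0, 0.0))


class TestCsvIngest:
    def test_minutes_converted(self, tmp_path):
        p = tmp_path / "tc.csv"
        p.write_text(
            "time_min,POPE,rest\n0,0.35,0.65\n1,0.30,0.70\n"
            "2,0.26,0.74\n3,0.23,0.77\n"
        )
        tc = read_timecourse_csv(str(p))
        assert tc.times_s[1] == pytest.approx(60.0)

    def test_closure_violation_on_ingest(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "time_s,POPE,rest\n0,0.35,0.60\n1,0.30,0.70\n"
            "2,0.26,0.74\n3,0.23,0.77\n"
        )
        with pytest.raises(KineticsError, match="closure"):
            read_timecourse_csv(str(p))
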