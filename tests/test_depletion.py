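"""In vitro clearance estimation: fits, window selection, QC, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishbcf import (
    InsufficientDataError,
    InvalidInputError,
    WindowPolicy,
    clint_from_k,
    estimate_clearance,
    fit_first_order,
    normalize_to_first,
    qc_inactivated,
    select_linear_window,
    summarize_runs,
)
from fishbcf.depletion import LN10, STANDARD_TIMES_H, intra_assay_cv


class TestNormalize:
    def test_rescales_first_point_to_one(self, tc_factory):
        tc = tc_factory([0, 1, 2, 3], [2.0, 1.0, 0.5, 0.25])
        out = normalize_to_first(tc)
        assert np.allclose(out.concentrations, [1.0, 0.5, 0.25, 0.125])

    def test_constant_series_maps_to_ones(self, tc_factory):
        out = normalize_to_first(tc_factory([0, 1, 2, 3], [3, 3, 3, 3]))
        assert np.allclose(out.concentrations, 1.0)

    def test_zero_first_value_rejected(self, tc_factory):
        with pytest.raises(InvalidInputError):
            normalize_to_first(tc_factory([0, 1, 2, 3], [0.0, 1, 1, 1]))

    def test_slope_unaffected_by_normalization(self, tc_factory, exact_exponential):
        t, c, k, _ = exact_exponential
        tc = tc_factory(t, c)
        fit_raw = fit_first_order(tc.times, tc.concentrations)
        fit_norm = fit_first_order(t, normalize_to_first(tc).concentrations)
        assert fit_norm.k == pytest.approx(fit_raw.k, rel=1e-12)


class TestFitFirstOrder:
    def test_exact_exponential_recovered_to_ten_digits(self, exact_exponential):
        t, c, k, _ = exact_exponential
        est = fit_first_order(t, c)
        assert est.k == pytest.approx(k, rel=1e-10)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.k == pytest.approx(-LN10 * est.slope_log10, rel=1e-12)

    def test_flat_series_gives_zero_rate(self):
        est = fit_first_order([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
        assert est.k == 0.0
        assert est.r_squared == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        k=st.floats(0.01, 3.0),
        c0=st.floats(0.1, 10.0),
        scale=st.floats(1e-3, 1e3),
    )
    def test_exact_recovery_and_unit_invariance(self, k, c0, scale):
        """Noiseless exponentials are inverted exactly; clint is unit-invariant."""
        t = np.array(STANDARD_TIMES_H)
        c = c0 * np.exp(-k * t)
        est = fit_first_order(t, c)
        est_scaled = fit_first_order(t, scale * c)
        assert est.k == pytest.approx(k, rel=1e-9)
        assert est_scaled.k == pytest.approx(est.k, rel=1e-9)

    def test_monotone_decreasing_data_gives_nonnegative_k(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = np.sort(rng.uniform(0.01, 10.0, size=6))[::-1]
            assert fit_first_order(np.arange(6.0), c).k >= 0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_first_order([0, 1], [1.0, 0.5])

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_first_order([0, 1, 2], [1.0, 0.5, 0.0])

    def test_window_restricts_fit(self, exact_exponential):
        t, c, k, _ = exact_exponential
        c = c.copy()
        c[-1] *= 10  # corrupt last point
        est = fit_first_order(t, c, window=range(len(t) - 1))
        assert est.k == pytest.approx(k, rel=1e-10)


class TestWindowSelection:
    def test_plateau_at_final_point_excluded(self, tc_factory):
        t = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 4.0])
        c = 2.0 * np.exp(-0.6 * t)
        c[-1] = c[-2]  # activity stops: 4 h sample plateaus
        window = select_linear_window(tc_factory(t, c))
        assert window == tuple(range(len(t) - 1))

    def test_log_linear_series_keeps_full_window(self, tc_factory, exact_exponential):
        t, c, _, _ = exact_exponential
        assert select_linear_window(tc_factory(t, c)) == tuple(range(len(t)))

    def test_floor_of_three_points_enforced(self, tc_factory):
        tc = tc_factory([0, 1, 2, 3], [2.0, 1.0, 0.5, 0.25])
        with pytest.raises(InsufficientDataError):
            select_linear_window(tc, WindowPolicy(max_drop=2))

    def test_loq_excludes_low_points(self, tc_factory):
        t = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 4.0])
        c = 2.0 * np.exp(-1.5 * t)
        window = select_linear_window(tc_factory(t, c), WindowPolicy(loq=c[-1]))
        assert len(t) - 1 not in window


class TestClintAndQC:
    @pytest.mark.parametrize(
        "k, density, expected",
        [(0.575, 2.0, 0.2875), (0.0, 2.0, 0.0), (0.4, 1.0, 0.4)],
    )
    def test_clint_arithmetic(self, k, density, expected):
        assert clint_from_k(k, density) == pytest.approx(expected)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(InvalidInputError):
            clint_from_k(0.5, 0.0)

    @pytest.mark.parametrize(
        "live, dead, passed, ratio",
        [
            (0.5, 0.02, True, 0.04),
            (0.5, 0.03, False, 0.06),
            (0.5, 0.0, True, 0.0),
            (0.5, 0.025, True, 0.05),  # exactly at the 5 % threshold
        ],
    )
    def test_dead_cell_threshold(self, live, dead, passed, ratio):
        res = qc_inactivated(live, dead)
        assert res.passed is passed
        assert res.ratio == pytest.approx(ratio)

    def test_nonpositive_live_rate_flags_undefined(self):
        res = qc_inactivated(0.0, 0.01)
        assert res.undefined and res.passed is None and res.ratio is None


class TestRunSummary:
    def test_mean_sd_cv(self):
        s = summarize_runs([0.1, 0.2, 0.3])
        assert s.mean_clint == pytest.approx(0.2)
        assert s.sd_clint == pytest.approx(0.1)
        assert s.cv_percent == pytest.approx(50.0)

    def test_cv_consistent_with_reported_rounding(self):
        # a run set with mean 0.250 and SD 0.151 has CV 60.4 %, which rounds
        # consistently with a reported 60.5 % (computed before rounding)
        cv = 100.0 * 0.151 / 0.250
        assert cv == pytest.approx(60.4)
        assert abs(cv - 60.5) < 0.5

    def test_identical_values_cv_zero(self):
        assert summarize_runs([0.2, 0.2, 0.2]).cv_percent == pytest.approx(0.0)

    def test_single_run_has_no_sd(self):
        s = summarize_runs([0.2])
        assert s.mean_clint == 0.2 and s.sd_clint is None and s.cv_percent is None

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_runs([])


class TestRunLevel:
    def test_estimate_clearance_noiseless_run(self, tc_factory, exact_exponential):
        t, c, k, _ = exact_exponential
        live = [tc_factory(t, c, replicate_id=r) for r in (1, 2, 3)]
        dead = tc_factory(t, 2.0 * np.exp(-0.01 * t), condition="inactivated")
        est = estimate_clearance(live, dead)
        assert est.k == pytest.approx(k, rel=1e-10)
        assert est.clint == pytest.approx(k / 2.0, rel=1e-10)
        assert est.qc.passed and est.qc.ratio == pytest.approx(0.02, rel=1e-9)

    def test_intra_assay_cv_zero_for_identical_replicates(self, tc_factory, exact_exponential):
        t, c, _, _ = exact_exponential
        live = [tc_factory(t, c, replicate_id=r) for r in (1, 2, 3)]
        assert intra_assay_cv(live) == pytest.approx(0.0, abs=1e-9)

    def test_intra_assay_cv_nonnegative_on_noisy_replicates(self, tc_factory, exact_exponential):
        t, c, _, _ = exact_exponential
        rng = np.random.default_rng(11)
        live = [
            tc_factory(t, c * rng.lognormal(0, 0.1, size=t.size), replicate_id=r)
            for r in (1, 2, 3)
        ]
        assert intra_assay_cv(live) > 0
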