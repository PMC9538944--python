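"""TG 305 evaluation: TWA water concentration, BCF_SS, depuration fit, growth."""

import numpy as np
import pandas as pd
import pytest

from fishbcf import (
    ChemicalProps,
    FishPhysiology,
    FishSeries,
    InsufficientDataError,
    InvalidInputError,
    StudyScenario,
    WaterSeries,
    analyze_study,
    detect_plateau,
    fit_depuration,
    growth_rate,
    simulate_tg305,
    steady_state_bcf,
    twa_concentration,
)


def fish_frame(rows):
    return FishSeries(pd.DataFrame(rows, columns=["day", "phase", "fish_id",
                                                  "conc_ng_kg", "weight_g"]))


def depuration_series(days, conc, weight=10.0):
    rows = [(d, "depuration", f"f{i}", c, weight) for i, (d, c) in enumerate(zip(days, conc))]
    return fish_frame(rows)


class TestTWA:
    def test_constant_series(self):
        ws = WaterSeries(days=[0, 3, 9, 14], concentrations=[5, 5, 5, 5])
        assert twa_concentration(ws) == pytest.approx(5.0, rel=1e-12)

    def test_step_series_equal_weights(self):
        ws = WaterSeries(days=[0, 7, 7, 14], concentrations=[4, 4, 8, 8])
        assert twa_concentration(ws) == pytest.approx(6.0, rel=1e-12)

    def test_refinement_invariance_piecewise_linear(self):
        days = np.array([0.0, 2.0, 9.0, 14.0, 21.0, 35.0])
        conc = np.array([5.0, 7.0, 6.0, 9.0, 4.0, 8.0])
        coarse = twa_concentration(WaterSeries(days=days, concentrations=conc))
        dense_days = np.unique(np.concatenate([days, np.linspace(0, 35, 3501)]))
        dense_conc = np.interp(dense_days, days, conc)
        dense = twa_concentration(WaterSeries(days=dense_days, concentrations=dense_conc))
        assert dense == pytest.approx(coarse, abs=1e-12)

    def test_single_sample_returns_value(self):
        ws = WaterSeries(days=[3.0], concentrations=[7.7])
        assert twa_concentration(ws) == 7.7

    def test_empty_window_rejected(self):
        ws = WaterSeries(days=[0, 7], concentrations=[5, 5])
        with pytest.raises(InsufficientDataError):
            twa_concentration(ws, window=(20.0, 30.0))


class TestSteadyStateBcf:
    def test_mean_over_twa(self):
        fs = fish_frame([(35, "uptake", f"f{i}", 140.0, 10.0) for i in range(4)])
        res = steady_state_bcf(fs, twa=1.0, plateau_days=[35])
        assert res.bcf_ss == pytest.approx(140.0)

    def test_identical_fish_constant_water_exact(self):
        fs = fish_frame(
            [(d, "uptake", f"f{d}{i}", 600.0, 10.0) for d in (28, 31, 35) for i in range(4)]
        )
        assert steady_state_bcf(fs, 3.0, [28, 31, 35]).bcf_ss == pytest.approx(200.0, rel=1e-12)

    def test_forward_simulation_noise_free(self):
        sc = StudyScenario(water_cv=0.0, fish_noise_cv=0.0, weight_noise_cv=0.0, seed=3)
        water, fish = simulate_tg305(sc)
        twa = twa_concentration(water)
        res = steady_state_bcf(fish, twa, list(sc.plateau_days))
        assert res.bcf_ss == pytest.approx(sc.true_bcf_ss, rel=1e-10)

    def test_nonpositive_twa_rejected(self):
        fs = fish_frame([(35, "uptake", "f1", 140.0, 10.0)])
        with pytest.raises(InvalidInputError):
            steady_state_bcf(fs, 0.0, [35])


class TestDepurationFit:
    def test_exact_exponential_recovery(self):
        days = np.array([4.0, 10.0, 21.0, 35.0])
        conc = 1000.0 * np.exp(-0.1 * days)
        fit = fit_depuration(depuration_series(days, conc))
        assert fit.kT == pytest.approx(0.1, rel=1e-10)
        assert fit.cf0 == pytest.approx(1000.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_unit_invariance(self):
        days = np.array([4.0, 10.0, 21.0, 35.0])
        conc = 1000.0 * np.exp(-0.1 * days)
        a = fit_depuration(depuration_series(days, conc))
        b = fit_depuration(depuration_series(days, conc * 1e3))
        assert b.kT == pytest.approx(a.kT, rel=1e-12)

    def test_no_depuration_gives_zero_slope(self):
        days = np.array([4.0, 10.0, 21.0, 35.0])
        fit = fit_depuration(depuration_series(days, np.full(4, 500.0)))
        assert fit.kT == pytest.approx(0.0, abs=1e-14)

    def test_too_few_days_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_depuration(depuration_series([4.0, 10.0], [900.0, 500.0]))

    def test_nonpositive_concentrations_excluded_with_warning(self):
        days = np.array([4.0, 10.0, 21.0, 35.0])
        conc = 1000.0 * np.exp(-0.1 * days)
        fs = depuration_series(np.append(days, 36.0), np.append(conc, 0.0))
        with pytest.warns(UserWarning):
            fit = fit_depuration(fs)
        assert fit.kT == pytest.approx(0.1, rel=1e-10)

    def test_noisy_recovery_median_within_five_percent(self):
        # 15 % lognormal noise, 4 fish/day
        true_kt = 0.12
        rels = []
        for seed in range(200):
            sc = StudyScenario(k2=0.03, kE=0.01, kG=0.005, kB=true_kt - 0.045,
                               fish_noise_cv=0.15, seed=seed)
            _, fish = simulate_tg305(sc)
            rels.append(fit_depuration(fish).kT / sc.kT - 1.0)
        assert abs(np.median(rels)) < 0.05


class TestGrowthRate:
    def test_doubling_in_35_days(self):
        rows = [(0, "uptake", "a", 100.0, 10.0), (35, "uptake", "b", 100.0, 20.0)]
        assert growth_rate(fish_frame(rows)) == pytest.approx(np.log(2) / 35, rel=1e-10)

    def test_constant_weights(self):
        rows = [(d, "uptake", f"f{d}", 100.0, 15.0) for d in (0, 14, 35)]
        assert growth_rate(fish_frame(rows)) == pytest.approx(0.0, abs=1e-14)

    def test_noisy_recovery_within_ten_percent(self):
        rels = []
        for seed in range(200):
            sc = StudyScenario(kg_weight=0.0198, weight_noise_cv=0.10, seed=seed)
            _, fish = simulate_tg305(sc)
            rels.append(growth_rate(fish) / sc.kg_weight - 1.0)
        assert abs(np.median(rels)) < 0.10

    def test_single_day_rejected(self):
        with pytest.raises(InsufficientDataError):
            growth_rate(fish_frame([(0, "uptake", "a", 1.0, 10.0)]))


class TestPlateauAndPipeline:
    def test_detect_plateau_finds_flat_tail(self):
        rows = []
        for d, c in [(0, 10.0), (7, 200.0), (14, 600.0), (21, 980.0),
                     (28, 1000.0), (31, 1001.0), (35, 999.0)]:
            for i in range(4):
                rows.append((d, "uptake", f"f{d}{i}", c * (1 + 0.01 * (i - 1.5)), 10.0))
        days = detect_plateau(fish_frame(rows))
        assert set(days) >= {28.0, 31.0, 35.0}
        assert 7.0 not in days and 0.0 not in days

    def test_end_to_end_recovers_kb_noise_free(self):
        phys = FishPhysiology(species="carp", body_mass=0.0446, temperature=21.0,
                              lipid_fraction=0.0957, liver_fraction=0.0174,
                              do_saturation=0.77)
        chem = ChemicalProps(name="methoxychlor", log_kow=5.08)
        from fishbcf import compute_rate_constants

        rates = compute_rate_constants(phys, chem)
        kb_true = 0.08
        sc = StudyScenario(
            k1=rates.k1, k2=rates.k2, kE=rates.kE, kG=rates.kG, kB=kb_true,
            water_cv=0.0, fish_noise_cv=0.0, weight_noise_cv=0.0, seed=5,
        )
        water, fish = simulate_tg305(sc)
        ev = analyze_study(water, fish, phys, chem, plateau_days=list(sc.plateau_days))
        assert ev.depuration.kT == pytest.approx(sc.kT, rel=1e-10)
        assert ev.in_vivo_kb.kb == pytest.approx(kb_true, rel=1e-9)
        assert ev.in_vivo_kb.distinguishable_from_zero
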