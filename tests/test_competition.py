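import numpy as np
import pytest

from chemevo.chemostat import (
    LN2,
    ChemostatConfig,
    ChemostatError,
    StrainParams,
    WashoutError,
    steady_state,
)
from chemevo.competition import (
    EmergenceSpec,
    FractionSeries,
    calibrate_logistic,
    crossing_generation,
    logistic_fraction,
    predict_competition,
    selection_per_generation,
    selection_rate,
    simulate_washin,
    stochastic_emergence_time,
    time_to_fraction,
)

T_445 = 445 * LN2 / 0.5  # hours to generation 445 at D = 0.5


class TestSelectionRate:
    def test_identical_strains_neutral(self, parent, reactor):
        twin = StrainParams("twin", parent.mu_max, parent.K_M)
        assert selection_rate(parent, twin, reactor) == pytest.approx(0.0)

    def test_derived_value(self, parent, mutant, reactor):
        # S* = 0.25, mu_m = 0.55*0.25/0.26, minus D = 0.5
        expect = 0.55 * 0.25 / 0.26 - 0.5
        s = selection_rate(parent, mutant, reactor)
        assert s == pytest.approx(expect)
        assert s > 0

    def test_matches_early_log_slope_of_ratio(self, parent, mutant, reactor):
        # oracle: early slope of log(x_m/x_p) in the full ODE
        em = EmergenceSpec(0.0, 1e-6, "frequency")
        traj, _ = simulate_washin(parent, mutant, reactor, em, t_end=20.0,
                                  t_eval=np.linspace(0, 20, 21))
        logratio = np.log(traj.X[1:, 1] / traj.X[1:, 0])
        slope = np.polyfit(traj.times[1:], logratio, 1)[0]
        assert slope == pytest.approx(
            selection_rate(parent, mutant, reactor), rel=1e-3
        )

    def test_worse_competitor_negative(self, parent, reactor):
        worse = StrainParams("worse", parent.mu_max, parent.K_M * 3)
        assert selection_rate(parent, worse, reactor) < 0

    def test_washout_precondition(self, parent, mutant):
        cfg = ChemostatConfig(D=0.75, S_in=25.0)
        with pytest.raises(WashoutError):
            selection_rate(parent, mutant, cfg)

    def test_invariant_under_km_rescaling(self, parent, mutant, reactor):
        c = 4.2
        p2 = StrainParams("p", parent.mu_max, parent.K_M * c)
        m2 = StrainParams("m", mutant.mu_max, mutant.K_M * c)
        assert selection_rate(p2, m2, reactor) == pytest.approx(
            selection_rate(parent, mutant, reactor)
        )


class TestEmergenceSpec:
    def test_frequency_bounds(self):
        with pytest.raises(ChemostatError):
            EmergenceSpec(0.0, 0.0, "frequency")
        with pytest.raises(ChemostatError):
            EmergenceSpec(0.0, 1.0, "frequency")

    def test_absolute_positive(self):
        with pytest.raises(ChemostatError):
            EmergenceSpec(0.0, 0.0, "absolute")

    def test_generation_time_unit(self):
        em = EmergenceSpec(70.0, 1e-4, "frequency", time_unit="generations")
        assert em.t_emerge_hours(0.5) == pytest.approx(70 * LN2 / 0.5)


class TestSimulateWashin:
    def test_neutral_fraction_constant(self, parent, reactor):
        twin = StrainParams("twin", parent.mu_max, parent.K_M)
        em = EmergenceSpec(0.0, 0.25, "frequency")
        _, fs = simulate_washin(parent, twin, reactor, em, t_end=300.0)
        assert np.allclose(fs.fraction, 0.25, atol=1e-9)

    def test_mutant_absent_before_emergence(self, parent, mutant, reactor):
        em = EmergenceSpec(50.0, 1e-3, "frequency")
        traj, fs = simulate_washin(parent, mutant, reactor, em, t_end=200.0,
                                   t_eval=np.linspace(0, 200, 201))
        assert np.all(fs.fraction[traj.times < 50.0] == 0.0)
        assert np.all(fs.fraction[traj.times > 51.0] > 0.0)

    def test_fraction_monotone_when_beneficial(self, parent, mutant, reactor,
                                               emergence):
        _, fs = simulate_washin(parent, mutant, reactor, emergence,
                                t_end=T_445)
        rising = fs.fraction[fs.fraction < 1.0 - 1e-12]
        assert np.all(np.diff(rising) > 0)

    def test_reaches_097_before_generation_445(self, parent, mutant, reactor):
        em = EmergenceSpec(0.0, 1e-6, "frequency")
        _, fs = simulate_washin(parent, mutant, reactor, em, t_end=T_445,
                                n_points=892)
        g97 = crossing_generation(fs, 0.97)
        assert g97 < 445
        assert fs.fraction[-1] >= 0.97

    def test_emergence_after_end_rejected(self, parent, mutant, reactor):
        em = EmergenceSpec(500.0, 1e-3, "frequency")
        with pytest.raises(ChemostatError):
            simulate_washin(parent, mutant, reactor, em, t_end=100.0)

    def test_frequency_conservation(self, parent, mutant, reactor, emergence):
        traj, fs = simulate_washin(parent, mutant, reactor, emergence,
                                   t_end=T_445)
        total = traj.X.sum(axis=1)
        parent_frac = traj.X[:, 0] / total
        assert np.allclose(parent_frac + fs.fraction, 1.0, atol=1e-12)

    def test_km_ratio_invariance(self, parent, mutant, reactor, emergence):
        # fraction dynamics depend on the K_M ratio; residual O(K_M/S_in)
        _, fs0 = simulate_washin(parent, mutant, reactor, emergence,
                                 t_end=T_445, n_points=90)
        for c in (0.5, 2.0):
            p = StrainParams("p", parent.mu_max, parent.K_M * c)
            m = StrainParams("m", mutant.mu_max, mutant.K_M * c)
            _, fs = simulate_washin(p, m, reactor, emergence,
                                    t_end=T_445, n_points=90)
            assert np.max(np.abs(fs.fraction - fs0.fraction)) < 2e-3

    def test_yield_amount_invariance_absolute_mode(self, parent, mutant,
                                                   reactor):
        # shared-yield culture: scaling yield and emergence biomass jointly
        # leaves the fraction series unchanged
        amount = 1e-3 * steady_state(parent, reactor).x[0]
        em = EmergenceSpec(0.0, amount, "absolute")
        _, fs0 = simulate_washin(parent, mutant, reactor, em, t_end=600.0,
                                 n_points=61)
        c = 2.5
        p = StrainParams("p", parent.mu_max, parent.K_M, c)
        m = StrainParams("m", mutant.mu_max, mutant.K_M, c)
        em_c = EmergenceSpec(0.0, amount * c, "absolute")
        _, fs = simulate_washin(p, m, reactor, em_c, t_end=600.0, n_points=61)
        assert np.max(np.abs(fs.fraction - fs0.fraction)) < 1e-6

    def test_crosses_any_threshold_in_finite_time(self, parent, mutant,
                                                  reactor, emergence):
        _, fs = simulate_washin(parent, mutant, reactor, emergence,
                                t_end=2 * T_445)
        for thr in (0.1, 0.5, 0.9, 0.99):
            assert np.isfinite(crossing_generation(fs, thr))


class TestLogistic:
    def test_neutral_constant(self):
        assert logistic_fraction(0.5, 0.0, 123.0) == pytest.approx(0.5)

    def test_boundary_rejected(self):
        for f0 in (0.0, 1.0):
            with pytest.raises(ChemostatError):
                logistic_fraction(f0, 0.1, 10.0)

    def test_calibrated_endpoint(self):
        # 1% at g70, 50% at g210 -> >= 97% by g445
        f0, s = calibrate_logistic(70.0, 0.01, 210.0, 0.5)
        assert logistic_fraction(f0, s, 445.0) >= 0.97

    def test_time_to_fraction_inverse(self):
        f0, s = 1e-4, 0.04
        g = time_to_fraction(f0, s, 0.5)
        assert logistic_fraction(f0, s, g) == pytest.approx(0.5)

    def test_matches_ode_in_rise_phase(self, parent, mutant, reactor):
        # agreement holds while residual substrate stays near the parent
        # steady state; within a 2% substrate window the error is < 2%
        em = EmergenceSpec(0.0, 5e-4, "frequency")
        traj, fs = simulate_washin(parent, mutant, reactor, em,
                                   t_end=T_445, n_points=446)
        s_gen = selection_per_generation(parent, mutant, reactor)
        fl = logistic_fraction(em.amount, s_gen, fs.generations)
        S_star = steady_state(parent, reactor).S
        near = np.abs(traj.S - S_star) / S_star <= 0.02
        assert np.max(np.abs(fs.fraction[near] - fl[near])) < 0.02
        within5 = np.abs(traj.S - S_star) / S_star <= 0.05
        assert np.max(np.abs(fs.fraction[within5] - fl[within5])) < 0.04

    def test_f0_01_matches_ode(self, parent, mutant, reactor):
        em = EmergenceSpec(0.0, 0.1, "frequency")
        traj, fs = simulate_washin(parent, mutant, reactor, em,
                                   t_end=200.0, n_points=201)
        s_gen = selection_per_generation(parent, mutant, reactor)
        fl = logistic_fraction(0.1, s_gen, fs.generations)
        S_star = steady_state(parent, reactor).S
        near = np.abs(traj.S - S_star) / S_star <= 0.02
        assert np.max(np.abs(fs.fraction[near] - fl[near])) < 0.02


class TestPredictCompetition:
    def test_neutral_flat(self, parent):
        twin = StrainParams("twin", parent.mu_max, parent.K_M)
        pred = predict_competition(parent, twin, [0.2, 0.3], f0=0.1,
                                   horizon=100.0)
        for fs in pred.series.values():
            assert np.allclose(fs.fraction, 0.1, atol=1e-9)

    def test_mutant_wins_at_all_rates(self, parent, mutant):
        Ds = [0.2, 0.3, 0.5]
        pred = predict_competition(parent, mutant, Ds, f0=0.1, horizon=445.0)
        for D in Ds:
            fs = pred.series[D]
            # oracle: sign of the selection rate at each D
            assert selection_rate(parent, mutant,
                                  ChemostatConfig(D=D, S_in=25.0)) > 0
            assert fs.fraction[-1] > fs.fraction[0]
            assert np.all(np.diff(fs.fraction) > -1e-12)

    def test_reports_crossings(self, parent, mutant):
        pred = predict_competition(parent, mutant, [0.5], f0=0.1,
                                   horizon=445.0)
        row = pred.crossings.iloc[0]
        assert row["g_half"] < row["g_97"] < 445

    def test_horizon_zero(self, parent, mutant):
        pred = predict_competition(parent, mutant, [0.3], f0=0.1, horizon=0.0)
        fs = pred.series[0.3]
        assert len(fs) == 1
        assert fs.fraction[0] == pytest.approx(0.1)

    def test_washout_diagnosis_names_both_limits(self, parent, mutant):
        with pytest.raises(WashoutError, match="0.7.*0.55|0.55.*0.7"):
            predict_competition(parent, mutant, [0.6], f0=0.1, horizon=10.0)


class TestFractionSeries:
    def test_validation(self):
        with pytest.raises(ChemostatError):
            FractionSeries(generations=[0, 1], fraction=[0.5, 1.5])
        with pytest.raises(ChemostatError):
            FractionSeries(generations=[1, 0], fraction=[0.5, 0.5])

    def test_csv_roundtrip(self, tmp_path):
        fs = FractionSeries(
            generations=[0.0, 20.0, 40.0], fraction=[0.0, 0.1, 0.4],
            depth=[500, 500, 500], ci_low=[0.0, 0.07, 0.35],
            ci_high=[0.01, 0.13, 0.45],
        )
        path = tmp_path / "f.csv"
        fs.to_csv(path, header_comment="x")
        back = FractionSeries.from_csv(path)
        assert np.allclose(back.fraction, fs.fraction)
        assert np.allclose(back.depth, fs.depth)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("generation,depth\n0,100\n")
        with pytest.raises(ChemostatError, match="fraction"):
            FractionSeries.from_csv(path)


def test_stochastic_emergence_seeded():
    t1 = stochastic_emergence_time(0.01, seed=5)
    t2 = stochastic_emergence_time(0.01, seed=5)
    assert t1 == t2 > 0
    with pytest.raises(ChemostatError):
        stochastic_emergence_time(0.0, seed=5)
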