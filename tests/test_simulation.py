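"""Integration, terminal-cycle detection, summary metrics and half-life."""

import io
import json

import numpy as np
import pytest

import lipbpk as L


class TestSimulate:
    def test_single_dose_plasma_peaks_at_end_of_absorption(self, params):
        """Plasma peaks when the 4-h controlled release ends (~240 min)."""
        traj = L.simulate_events(
            params, [L.DoseEvent(0.0, 900.0, 240.0)], horizon_min=2880.0
        )
        plasma = traj.concentrations["plasma"]
        t_peak = traj.times[int(np.argmax(plasma))]
        assert abs(t_peak - 240.0) <= 5.0

    def test_zero_dose_trajectory_is_identically_zero(self, params):
        traj = L.simulate_events(params, [], horizon_min=1440.0)
        for name in L.STATE_ORDER:
            np.testing.assert_array_equal(
                traj.concentrations[name], np.zeros_like(traj.times)
            )

    def test_grid_spacing_and_boundaries(self, params):
        traj = L.simulate(params, L.PRESETS["450/900"], n_cycles=1)
        dt = np.diff(traj.times)
        assert dt.max() <= 1.0 + 1e-9
        for boundary in (0.0, 240.0, 720.0, 960.0, 1440.0):
            assert np.any(np.isclose(traj.times, boundary))

    def test_partition_ratios_reached_without_clearance(self, params):
        """With kk=0 the system relaxes to C_i/C_P = R_i in every tissue."""
        p0 = params.with_renal_clearance(0.0)
        traj = L.simulate_events(
            p0, [L.DoseEvent(0.0, 300.0, 240.0)], horizon_min=6000.0
        )
        c_p = traj.concentrations["plasma"][-1]
        for name in L.PERIPHERAL_COMPARTMENTS:
            ratio = traj.concentrations[name][-1] / c_p
            assert ratio == pytest.approx(p0.partition(name), rel=1e-3)

    def test_concentrations_stay_nonnegative(self, params):
        traj = L.simulate(params, L.PRESETS["450/900"], n_cycles=2)
        for name in L.STATE_ORDER:
            assert traj.concentrations[name].min() >= -1e-9


class TestTerminalCycle:
    def test_converges_and_flags(self, terminal_summary):
        s = terminal_summary("450/900")
        assert s.converged
        assert 2 <= s.n_cycles_run <= 60

    def test_average_never_exceeds_peak(self, terminal_summary):
        s = terminal_summary("450/900")
        for name, stats in s.compartments.items():
            assert stats.average <= stats.peak + 1e-12, name

    def test_nonconvergence_reported_not_raised(self, params):
        s = L.find_terminal_cycle(params, L.PRESETS["300/300"], max_cycles=2)
        assert not s.converged
        assert s.n_cycles_run == 2

    def test_loose_tolerance_changes_metrics_under_one_percent(
        self, params, terminal_summary
    ):
        tight = terminal_summary("300/300").compartments["fetus"]
        loose = L.find_terminal_cycle(
            params, L.PRESETS["300/300"], tolerance=1e-3
        ).compartments["fetus"]
        assert loose.peak == pytest.approx(tight.peak, rel=1e-2)
        assert loose.average == pytest.approx(tight.average, rel=1e-2)

    def test_terminal_flow_balance_identities(self, params, terminal_summary):
        """At periodic steady state: avg(C_U)/R_U = avg(C_P),
        avg(C_F)/R_F = avg(C_U)/R_U, and absorption balances elimination."""
        s = terminal_summary("450/900")
        avg = {n: s.compartments[n].average for n in L.STATE_ORDER}
        r_u = params.partition("uterus")
        r_f = params.partition("fetus")
        assert avg["uterus"] / r_u == pytest.approx(avg["plasma"], rel=1e-2)
        assert avg["fetus"] / r_f == pytest.approx(avg["uterus"] / r_u, rel=1e-2)
        # dose rate (mEq/min) == kk * avg(C_K)/R_K, i.e. net cycle flux ~ 0
        dose_rate = L.cycle_dose_mEq(L.PRESETS["450/900"]) / 1440.0
        elim_rate = (
            params.renal_clearance
            * (avg["kidney"] / L.MEQ_PER_ML_TO_MEQ_PER_L)
            / params.partition("kidney")
        )
        assert elim_rate == pytest.approx(dose_rate, rel=1e-2)

    @pytest.mark.parametrize("name", ["450/900", "400/400/400"])
    def test_matches_analytic_flow_balance_oracle(
        self, params, terminal_summary, name
    ):
        s = terminal_summary(name)
        oracle = L.analytic_steady_state_average(params, L.PRESETS[name])
        for comp in L.STATE_ORDER:
            assert s.compartments[comp].average == pytest.approx(
                oracle[comp], rel=1e-2
            ), comp

    def test_equal_daily_dose_gives_equal_averages(self, terminal_summary):
        """Splitting a fixed daily dose cannot change the terminal average
        (linear system), while peaks strictly decrease with more doses."""
        s2 = terminal_summary("600/600").compartments["fetus"]
        s3 = terminal_summary("400/400/400").compartments["fetus"]
        s4 = terminal_summary("300/300/300/300").compartments["fetus"]
        assert s3.average == pytest.approx(s2.average, rel=1e-3)
        assert s4.average == pytest.approx(s2.average, rel=1e-3)
        assert s2.peak > s3.peak > s4.peak

    def test_grid_refinement_stable(self, params, terminal_summary):
        coarse = terminal_summary("300/300").compartments["fetus"]
        fine = L.find_terminal_cycle(
            params, L.PRESETS["300/300"], grid_dt=0.5
        ).compartments["fetus"]
        assert fine.peak == pytest.approx(coarse.peak, rel=1e-3)


class TestAnalyticOracle:
    def test_plasma_average_closed_form(self, params):
        """avg C_P = dosing rate / effective clearance, in mEq/L."""
        reg = L.PRESETS["400/400/400"]
        oracle = L.analytic_steady_state_average(params, reg)
        expected = (32.0 / 1440.0) / L.effective_clearance(params) * 1000.0
        assert oracle["plasma"] == pytest.approx(expected)
        assert oracle["fetus"] / oracle["plasma"] == pytest.approx(0.8)

    def test_doubling_dose_doubles_every_average(self, params):
        reg = L.PRESETS["300/300"]
        a1 = L.analytic_steady_state_average(params, reg)
        a2 = L.analytic_steady_state_average(params, reg.scaled(2.0))
        for name in L.STATE_ORDER:
            assert a2[name] == pytest.approx(2 * a1[name])

    def test_zero_clearance_has_no_steady_state(self, params):
        with pytest.raises(ValueError):
            L.analytic_steady_state_average(
                params.with_renal_clearance(0.0), L.PRESETS["300/300"]
            )


class TestHalfLife:
    def test_about_twelve_hours(self, params):
        assert L.estimate_half_life(params) == pytest.approx(12.0, abs=1.5)

    def test_one_pool_closed_form_cross_check(self, params):
        """ln2 * (V_P + Σ V_i R_i) / CL_eff ≈ 12.2 h.  The simulated
        peak-to-half time also includes the distribution phase, so agreement
        is loose (15%)."""
        v_eff = params.plasma_volume + sum(
            c.volume * c.partition for c in params.compartments.values()
        )
        closed = np.log(2) * v_eff / L.effective_clearance(params) / 60.0
        assert closed == pytest.approx(12.18, abs=0.05)
        simulated = L.estimate_half_life(params)
        assert simulated == pytest.approx(closed, rel=0.15)

    def test_doubled_clearance_shortens_half_life(self, params):
        fast = L.estimate_half_life(params.with_renal_clearance(40.0))
        slow = L.estimate_half_life(params)
        assert fast < 0.7 * slow

    def test_requires_single_dose_schedule(self, params):
        with pytest.raises(ValueError):
            L.estimate_half_life(params, L.PRESETS["450/900"])

    def test_short_horizon_raises_structured_error(self, params):
        with pytest.raises(L.HorizonError):
            L.estimate_half_life(params, horizon_min=300.0)


class TestWriters:
    def test_trajectory_csv_header_and_units_row(self, params):
        traj = L.simulate(params, L.PRESETS["300/300"], n_cycles=1)
        buf = io.StringIO()
        traj.to_csv(buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "# concentrations in mEq/L"
        assert lines[1].split(",") == [
            "time_min", "plasma", "brain", "thyroid", "bone",
            "gi_tract", "kidney", "uterus", "fetus",
        ]

    def test_cycle_summary_json(self, terminal_summary):
        buf = io.StringIO()
        terminal_summary("450/900").to_json(buf)
        doc = json.loads(buf.getvalue())
        assert doc["units"] == "mEq/L"
        assert doc["converged"] is True
        assert set(doc["compartments"]) == set(L.STATE_ORDER)
        fetal = doc["compartments"]["fetus"]
        assert set(fetal) == {"peak", "peak_time_min", "average"}
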