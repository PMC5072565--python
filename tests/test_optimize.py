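"""Tests for the MILP treatment-plan optimizer and its enumeration oracle."""

import numpy as np
import pytest

import cmlsched as cs
from cmlsched.optimize import (
    OTPInstance,
    brute_force_otp,
    build_milp,
    evaluate_schedule,
    solve_otp,
    state_upper_bounds,
)
from cmlsched.toxicity import ANCParams, check_feasible


def make_instance(maps, x0, M, objective="terminal_burden", toxicity="off", anc=None):
    return OTPInstance(x0=x0, maps=maps, horizon_M=M, objective=objective,
                       toxicity=toxicity, anc=anc)


class TestStateUpperBounds:
    def test_bounds_dominate_random_schedules(self, maps8, scenario_m351t):
        U = state_upper_bounds(maps8, scenario_m351t.x0, 8)
        rng = np.random.default_rng(5)
        for _ in range(50):
            sched = cs.TreatmentSchedule(tuple(rng.integers(0, 4, size=8)))
            monthly = cs.propagate_affine(scenario_m351t.x0, sched, maps8)
            states234 = np.swapaxes(monthly[:, 1:, :], 1, 2)  # (M+1, types, 3)
            assert np.all(states234 <= U * (1 + 1e-9))

    def test_single_drug_bounds_are_exact(self, synth1, scenario_m351t):
        """If every drug has the same dynamics, the bound equals the trajectory."""
        rates, dd = synth1
        birth = rates.birth.copy()
        death = rates.death.copy()
        for j in range(1, 4):
            birth[..., j] = birth[..., 0]
            death[..., j] = death[..., 0]
        uni = cs.DrugRateTable(birth, death)
        dd_uni = cs.DensityDependence.from_rates(uni, dd.K1, dd.K2)
        stem = cs.make_stem_trajectory(scenario_m351t.x0, uni, dd_uni, 4)
        maps = cs.precompute_affine_maps(uni, dd_uni, stem, 4)
        U = state_upper_bounds(maps, scenario_m351t.x0, 4)
        monthly = cs.propagate_affine(scenario_m351t.x0, cs.TreatmentSchedule((0,) * 4), maps)
        assert np.allclose(U, np.swapaxes(monthly[:, 1:, :], 1, 2), rtol=1e-12)

    def test_bounds_monotone_in_initial_state(self, maps8, scenario_m351t):
        U_small = state_upper_bounds(maps8, scenario_m351t.x0, 6)
        bigger = cs.SystemState(scenario_m351t.x0.abundance * 2.0)
        U_big = state_upper_bounds(maps8, bigger, 6)
        assert np.all(U_big >= U_small)


class TestBuildMilp:
    def test_single_month_structure(self, maps8, scenario_m351t):
        model, index = build_milp(make_instance(maps8, scenario_m351t.x0, 1))
        assert sum(model.integer) == 4
        assert index["z"].shape == (1, 4)

    def test_toxicity_off_has_no_anc_variables(self, maps8, scenario_m351t):
        model, index = build_milp(make_instance(maps8, scenario_m351t.x0, 3))
        assert "y" not in index
        assert not any(name.startswith("y_") for name in model.names)

    def test_fixed_schedule_lp_reproduces_propagation(self, maps8, scenario_m351t):
        """Pinning the binaries to a schedule makes the MILP an LP whose
        objective equals the affine simulator output."""
        from scipy.optimize import milp

        sched = cs.TreatmentSchedule((2, 0, 1, 3))
        inst = make_instance(maps8, scenario_m351t.x0, 4)
        model, index = build_milp(inst)
        for m, j_star in enumerate(sched):
            for j in range(4):
                v = int(index["z"][m, j])
                model.lb[v] = model.ub[v] = 1.0 if j == j_star else 0.0
        c, constraints, bounds, integrality = model.to_scipy()
        res = milp(c, constraints=constraints, bounds=bounds, integrality=integrality)
        assert res.status == 0
        from cmlsched.optimize import STATE_SCALE

        got = res.fun * STATE_SCALE + model.obj_const * STATE_SCALE
        expected = evaluate_schedule(scenario_m351t.x0, sched, maps8)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_lp_export(self, maps8, scenario_m351t, tmp_path):
        model, _ = build_milp(make_instance(maps8, scenario_m351t.x0, 2))
        path = tmp_path / "otp.lp"
        model.write_lp(path)
        text = path.read_text()
        assert text.startswith("Minimize")
        assert "Binaries" in text and "z_0_0" in text


class TestBruteForce:
    def test_single_month_enumerates_four_plans(self, maps8, scenario_m351t):
        inst = make_instance(maps8, scenario_m351t.x0, 1)
        sol = brute_force_otp(inst)
        objs = {
            j: evaluate_schedule(scenario_m351t.x0, cs.TreatmentSchedule((j,)), maps8)
            for j in range(4)
        }
        assert sol.objective_value == pytest.approx(min(objs.values()))
        assert sol.schedule.decisions[0] == min(objs, key=objs.get)

    def test_tiny_anc_margin_forces_holiday(self, maps8, scenario_m351t):
        """With only one drug-month of ANC headroom, two drug months are infeasible."""
        anc = ANCParams(y0=1400.0)  # any drug drops y below 1400-250 >= 1000 once only
        inst = make_instance(maps8, scenario_m351t.x0, 2, toxicity="hard_bound", anc=anc)
        sol = brute_force_otp(inst)
        assert 0 in sol.schedule.decisions
        ok, _ = check_feasible(sol.schedule, anc, "hard_bound")
        assert ok

    def test_cap_enforced(self, maps8, scenario_m351t):
        with pytest.raises(ValueError, match="brute force"):
            brute_force_otp(make_instance(maps8, scenario_m351t.x0, 8), cap=6)

    def test_infeasible_when_starting_neutropenic(self, maps8, scenario_m351t):
        anc = ANCParams(y0=500.0)
        sol = brute_force_otp(make_instance(maps8, scenario_m351t.x0, 2, toxicity="hard_bound", anc=anc))
        assert sol.status == "infeasible"


class TestSolveOtp:
    def test_dominant_drug_monotherapy(self, scenario_m351t):
        """A drug that strictly dominates the others is used every month."""
        rates, dd = cs.synthetic_params(42)
        birth = rates.birth.copy()
        # make dasatinib dominate: every other mode keeps holiday (no-kill) rates
        for j in (1, 3):
            birth[1:, :, j] = birth[1:, :, 0]
        dom = cs.DrugRateTable(birth, rates.death.copy())
        dd_dom = cs.DensityDependence.from_rates(dom, dd.K1, dd.K2)
        stem = cs.make_stem_trajectory(scenario_m351t.x0, dom, dd_dom, 4)
        maps = cs.precompute_affine_maps(dom, dd_dom, stem, 4)
        sol = solve_otp(make_instance(maps, scenario_m351t.x0, 4))
        assert sol.schedule.decisions == (2, 2, 2, 2)

    @pytest.mark.parametrize("toxicity", ["off", "hard_bound"])
    def test_matches_oracle_m4(self, maps8, scenario_m351t, toxicity):
        inst = make_instance(maps8, scenario_m351t.x0, 4, toxicity=toxicity)
        sol = solve_otp(inst)
        oracle = brute_force_otp(inst)
        assert sol.objective_value == pytest.approx(oracle.objective_value, rel=1e-6)

    def test_matches_oracle_average_objective(self, maps8, scenario_m351t):
        inst = make_instance(maps8, scenario_m351t.x0, 4, objective="average_burden")
        sol = solve_otp(inst)
        oracle = brute_force_otp(inst)
        assert sol.objective_value == pytest.approx(oracle.objective_value, rel=1e-6)

    def test_toxicity_never_improves_objective(self, maps8, scenario_m351t):
        free = solve_otp(make_instance(maps8, scenario_m351t.x0, 5))
        constrained = solve_otp(make_instance(maps8, scenario_m351t.x0, 5, toxicity="hard_bound"))
        assert constrained.objective_value >= free.objective_value * (1 - 1e-9)

    def test_returned_schedule_is_feasible(self, maps8, scenario_m351t):
        anc = ANCParams()
        sol = solve_otp(make_instance(maps8, scenario_m351t.x0, 6, toxicity="hard_bound", anc=anc))
        ok, _ = check_feasible(sol.schedule, anc, "hard_bound")
        assert ok

    def test_trigger_matches_oracle(self, maps8, scenario_m351t):
        anc = ANCParams(y0=1600.0)
        inst = make_instance(maps8, scenario_m351t.x0, 4, toxicity="trigger", anc=anc)
        sol = solve_otp(inst)
        oracle = brute_force_otp(inst)
        ok, _ = check_feasible(sol.schedule, anc, "trigger")
        assert ok
        assert sol.objective_value == pytest.approx(oracle.objective_value, rel=1e-6)

    def test_infeasible_reported(self, maps8, scenario_m351t):
        anc = ANCParams(y0=800.0)
        sol = solve_otp(make_instance(maps8, scenario_m351t.x0, 3, toxicity="hard_bound", anc=anc))
        assert sol.status == "infeasible"
        assert sol.schedule is None

    def test_self_consistency_with_ode(self, synth1, maps8, scenario_m351t):
        """The reported objective matches full ODE re-simulation to 1e-4."""
        rates, dd = synth1
        sol = solve_otp(make_instance(maps8, scenario_m351t.x0, 5))
        traj = cs.simulate_schedule_ode(scenario_m351t.x0, sol.schedule, rates, dd)
        ode_obj = cs.leukemic_burden(traj.monthly_states[-1])
        assert sol.objective_value == pytest.approx(ode_obj, rel=1e-4)

    def test_dominated_drug_never_changes_optimum(self, synth1, scenario_m351t):
        """Worsening an already-dominated mode leaves the optimum unchanged."""
        rates, dd = synth1
        variants = []
        for factor in (1.0, 3.0):  # imatinib birth rates at, then above, holiday level
            birth = rates.birth.copy()
            birth[1:, 1:, 3] = birth[1:, 1:, 0] * factor
            tab = cs.DrugRateTable(birth, rates.death.copy())
            ddv = cs.DensityDependence.from_rates(tab, dd.K1, dd.K2)
            stem = cs.make_stem_trajectory(scenario_m351t.x0, tab, ddv, 4)
            maps = cs.precompute_affine_maps(tab, ddv, stem, 4)
            variants.append(brute_force_otp(make_instance(maps, scenario_m351t.x0, 4)))
        assert variants[0].schedule == variants[1].schedule
        assert 3 not in variants[0].schedule.decisions
        assert variants[0].objective_value == pytest.approx(variants[1].objective_value, rel=1e-9)


class TestCompareSchedules:
    def test_identical_schedules_identical_rows(self, synth1, scenario_m351t):
        rates, dd = synth1
        sched = cs.TreatmentSchedule((2, 1, 0))
        table = cs.compare_schedules([sched, sched], scenario_m351t.x0, rates, dd,
                                     report_months=(2, 3))
        a, b = table.iloc[0], table.iloc[1]
        for col in table.columns:
            if col != "label":
                assert a[col] == b[col]

    def test_reports_requested_months(self, synth1, scenario_m351t):
        rates, dd = synth1
        table = cs.compare_schedules(
            [cs.TreatmentSchedule((1, 1, 1, 1))], scenario_m351t.x0, rates, dd,
            report_months=(2, 4), labels=["nilotinib"],
        )
        assert {"burden_m2", "leukemic_pct_m2", "burden_m4", "leukemic_pct_m4"} <= set(table.columns)
        assert table.loc[0, "burden_m4"] == table.loc[0, "terminal_burden"]
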