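"""Closed-loop pathway: internal-ligand maps, mass-action network, simulation."""

import math

import numpy as np
import pytest

from rsfcd.pathway import (
    ChemotaxisModel,
    FlagellarParams,
    LigandProgram,
    MethylationParams,
    ModelVariant,
    PhosphoNetworkParams,
    SolverOptions,
    assemble_model,
    flagellar_frequency,
    internal_ligand_model_I,
    internal_ligand_model_II_rhs,
    methylation_rhs,
    phospho_rhs,
)


class TestInternalLigandMaps:
    def test_model_I_identity_without_phospho(self):
        assert internal_ligand_model_I(100.0, 0.0, 0.0) == pytest.approx(100.0)

    def test_model_I_at_printed_totals(self):
        # full phosphorylation of the 3.2/13.2 uM CheY3/CheY4 pools
        assert internal_ligand_model_I(100.0, 3.2, 13.2) == pytest.approx(1000 / 26.4)

    def test_model_I_worst_case_attenuation_factor(self):
        L = 500.0
        Lt = internal_ligand_model_I(L, 3.2, 13.2)
        assert L / Lt == pytest.approx(2.64)

    def test_model_II_fixed_point_and_closed_form(self):
        assert internal_ligand_model_II_rhs(100.0, 100.0, 10.0) == 0.0
        # step 0 -> 100 uM: L_t(tau) = 100*(1 - 1/e)
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda t, y: [internal_ligand_model_II_rhs(y[0], 100.0, 10.0)],
                        (0, 10.0), [0.0], rtol=1e-12, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(100 * (1 - math.exp(-1)), rel=1e-8)

    def test_model_II_filter_is_linear_in_scale(self):
        # scaling L and the initial state scales the whole trajectory
        from scipy.integrate import solve_ivp
        for p in (2.0, 7.5):
            base = solve_ivp(lambda t, y: [internal_ligand_model_II_rhs(y[0], 100.0, 10.0)],
                             (0, 30), [20.0], rtol=1e-12, atol=1e-12)
            scaled = solve_ivp(lambda t, y: [internal_ligand_model_II_rhs(y[0], p * 100.0, 10.0)],
                               (0, 30), [p * 20.0], rtol=1e-12, atol=1e-12,
                               t_eval=base.t)
            np.testing.assert_allclose(scaled.y[0], p * base.y[0], rtol=1e-8)

    def test_model_II_confinement_after_step(self):
        from scipy.integrate import solve_ivp
        La, Lb = 100.0, 500.0
        sol = solve_ivp(lambda t, y: [internal_ligand_model_II_rhs(y[0], Lb, 10.0)],
                        (0, 200), [La], rtol=1e-10, atol=1e-10)
        assert np.all(sol.y[0] >= La - 1e-9)
        assert np.all(sol.y[0] < Lb)

    def test_nonpositive_time_constant_rejected(self):
        with pytest.raises(ValueError):
            internal_ligand_model_II_rhs(0.0, 1.0, 0.0)


class TestMethylationRHS:
    meth = MethylationParams()

    def test_fully_active_receptors_only_demethylate(self):
        dm, _ = methylation_rhs(1.0, 0.5, 1.0, 1.0, self.meth, ModelVariant("I"))
        assert dm == pytest.approx(-(self.meth.k_B1 + self.meth.k_B2))
        assert dm < 0

    def test_fully_inactive_receptors_only_methylate(self):
        dm, _ = methylation_rhs(0.0, 0.5, 1.0, 1.0, self.meth, ModelVariant("I"))
        assert dm == pytest.approx(self.meth.k_R)

    def test_model_III_drops_B2_from_membrane(self):
        dm_12, _ = methylation_rhs(0.5, 0.5, 1.0, 1.0, self.meth, ModelVariant("I"))
        dm_3, _ = methylation_rhs(0.5, 0.5, 1.0, 1.0, self.meth, ModelVariant("III"))
        assert dm_3 - dm_12 == pytest.approx(0.5 * self.meth.k_B2)

    def test_membrane_steady_activity_identity(self, model_I, steady_I_at_0):
        # at equilibrium a* = k_R / (k_R + k_B1*B1p* + k_B2*B2p*)
        y = steady_I_at_0
        B1p, B2p = y[7], y[8]
        meth = model_I.methylation
        a_star = meth.k_R / (meth.k_R + meth.k_B1 * B1p + meth.k_B2 * B2p)
        assert model_I._activity(y[0], 0.0, model_I.membrane) == pytest.approx(
            a_star, abs=1e-9)


class TestPhosphoRHS:
    params = PhosphoNetworkParams()

    def test_quiescent_network_is_stationary(self):
        dx = phospho_rhs(np.zeros(7), 0.0, 0.0, self.params)
        np.testing.assert_array_equal(dx, 0.0)

    def test_phosphoryl_flux_conservation(self, rng):
        # the A2p loss from transfers equals the sum of acceptor gains
        x = rng.uniform(0, 1, 7) * [5, 5, 3.2, 13.2, 10, 2, 2]
        dx = phospho_rhs(x, 0.37, 0.21, self.params)
        A2p, A34p = x[0], x[1]
        tot = self.params.totals
        xp = dict(zip(("Y3", "Y4", "Y6", "B1", "B2"), x[2:]))
        transfers_A2 = sum(self.params.k_transfer[f"A2->{j}"] * A2p * (tot[j] - xp[j])
                           for j in ("Y3", "Y4", "Y6", "B1", "B2"))
        auto = self.params.k_auto_A2 * 0.37 * (tot["A2"] - A2p)
        assert dx[0] == pytest.approx(auto - transfers_A2, rel=1e-12)
        gains = sum(dx[2:]) + sum(self.params.k_dephos[j] * xp[j] for j in xp)
        transfers_A34 = sum(self.params.k_transfer[f"A34->{j}"] * A34p * (tot[j] - xp[j])
                            for j in ("Y6", "B2"))
        assert gains == pytest.approx(transfers_A2 + transfers_A34, rel=1e-10)

    def test_cheA2_deletion_starves_Y3(self):
        model = assemble_model("I").with_mutations("cheA2_del")
        ss = model.steady_state(100.0)
        names = model.state_names
        assert ss[names.index("Y3p")] == pytest.approx(0.0, abs=1e-9)
        assert ss[names.index("Y4p")] == pytest.approx(0.0, abs=1e-9)
        # CheY6 still phosphorylated through the cytoplasmic branch
        assert ss[names.index("Y6p")] > 0.5

    def test_fixed_point_agrees_between_integration_and_root_solve(self):
        # two independent numerical routes at clamped activities
        from scipy.integrate import solve_ivp
        from scipy.optimize import root
        a, a_t = 0.3, 0.6
        fun = lambda x: phospho_rhs(x, a, a_t, self.params)
        sol_int = solve_ivp(lambda t, x: fun(x), (0, 200), np.zeros(7),
                            rtol=1e-12, atol=1e-12)
        sol_root = root(fun, sol_int.y[:, -1] * 0.5 + 0.1, method="hybr", tol=1e-13)
        np.testing.assert_allclose(sol_int.y[:, -1], sol_root.x, atol=1e-8)


class TestFlagellarOutput:
    params = FlagellarParams()

    def test_max_frequency_at_zero_phospho(self):
        assert flagellar_frequency(0.0, 0.0, 0.0, self.params) == 8.0

    def test_half_effect_point(self):
        # V = q: choose Y6p = q / (Y3p + Y4p)
        f = flagellar_frequency(2.0, 2.0, self.params.q / 4.0, self.params)
        assert f == pytest.approx(self.params.f_max / 2)

    def test_and_gate_silent_branches(self):
        assert flagellar_frequency(5.0, 5.0, 0.0, self.params) == 8.0
        assert flagellar_frequency(0.0, 0.0, 5.0, self.params) == 8.0

    def test_monotone_decreasing_in_each_cheY(self):
        f = [flagellar_frequency(1.0, 1.0, y6, self.params)
             for y6 in np.linspace(0.1, 20, 50)]
        assert np.all(np.diff(f) < 0)


class TestAssembly:
    def test_model_III_constant_cluster_size(self):
        model = assemble_model("III")
        assert model.membrane.N == 17.5
        assert model.cytoplasmic.N == 17.5

    def test_model_I_has_u_feedback_into_internal_ligand(self):
        model = assemble_model("I")
        y = model.steady_state(100.0)
        y_perturbed = y.copy()
        y_perturbed[model.state_names.index("Y3p")] += 1.0
        assert model.internal_ligand(100.0, y_perturbed) != pytest.approx(
            model.internal_ligand(100.0, y))

    def test_model_III_has_no_u_feedback(self):
        model = assemble_model("III")
        y = model.steady_state(100.0)
        y2 = y.copy()
        y2[model.state_names.index("Y3p")] += 1.0
        assert model.internal_ligand(100.0, y2) == model.internal_ligand(100.0, y)

    def test_cheB2_deletion_removes_B2_everywhere(self):
        model = assemble_model("I").with_mutations("cheB2_del")
        assert model.totals["B2"] == 0.0
        ss = model.steady_state(100.0)
        assert ss[model.state_names.index("B2p")] == pytest.approx(0.0, abs=1e-12)
        # cytoplasmic cluster has lost its only demethylase
        assert not model.cytoplasmic_demethylation_possible()

    def test_cheY4_overexpression_scales_total(self):
        model = assemble_model("I").with_mutations("cheY4_5x")
        assert model.totals["Y4"] == pytest.approx(5 * 13.2)

    def test_unknown_mutation_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant("I", mutations=frozenset({"cheZ_del"}))


class TestSteadyStateAndSimulate:
    def test_adaptation_across_backgrounds(self, log_models):
        # steady-state activities and flagellar output do not depend on L
        for vid, model in log_models.items():
            vals = []
            for L in (50.0, 100.0, 500.0, 1000.0):
                y = model.steady_state(L)
                x = y[model._x0:]
                vals.append([model._activity(y[0], L, model.membrane),
                             model._activity(y[1], model.internal_ligand(L, y),
                                             model.cytoplasmic),
                             flagellar_frequency(x[2], x[3], x[4], model.flagellar)])
            spread = np.ptp(np.array(vals), axis=0)
            assert np.all(spread < 1e-6), f"model {vid} adaptation spread {spread}"

    def test_steady_state_is_fixed_point_of_integration(self, model_I, steady_I_at_0):
        t = np.linspace(0.0, 200.0, 21)
        traj = model_I.simulate(LigandProgram.constant(0.0), t, steady_I_at_0)
        for name in ("a", "a_t", "f"):
            assert np.ptp(traj[name]) < 1e-8

    def test_structural_robustness_of_adaptation(self):
        # swapping the demethylation wiring (I/II style vs III style)
        # preserves adaptation of both clusters
        for vid in ("I", "III"):
            model = assemble_model(vid, activity_form="log")
            a_vals = []
            for L in (100.0, 1000.0):
                y = model.steady_state(L)
                a_vals.append(model._activity(y[0], L, model.membrane))
            assert a_vals[0] == pytest.approx(a_vals[1], abs=1e-8)

    def test_tethered_assay_schedule_transient_adapts_back(self, model_I, steady_I_at_0):
        t = np.linspace(0.0, 600.0, 601)
        traj = model_I.simulate(LigandProgram.tethered_assay_schedule(), t, steady_I_at_0)
        f = traj["f"]
        pre = f[t == 240.0][0]
        # visible transient after each step, return to baseline at the end
        assert np.max(np.abs(f - pre)) > 1.0
        assert abs(f[-1] - pre) < 1e-4

    def test_concentrations_bounded_on_random_programs(self, model_I, rng):
        for _ in range(10):
            n_steps = rng.integers(1, 4)
            bps = np.sort(rng.uniform(50, 550, n_steps))
            levels = rng.uniform(0, 2000, n_steps + 1)
            prog = LigandProgram(tuple(bps), tuple(levels))
            y0 = model_I.steady_state(levels[0])
            traj = model_I.simulate(prog, np.linspace(0, 600, 301), y0)
            for name in ("A2p", "A34p", "Y3p", "Y4p", "Y6p", "B1p", "B2p"):
                assert np.all(traj[name] >= 0.0)
                assert np.all(traj[name] <= model_I.totals[name[:-1]] + 1e-9)
            assert np.all(traj["a"] > 0) and np.all(traj["a"] < 1)
            assert np.all(traj["f"] >= 0) and np.all(traj["f"] <= 8.0 + 1e-9)

    def test_solver_tolerance_halving_stability(self, model_I, steady_I_at_0):
        t = np.linspace(0.0, 600.0, 301)
        prog = LigandProgram.tethered_assay_schedule()
        tight = model_I.with_(solver=SolverOptions(rtol=5e-11, atol=5e-13))
        f1 = model_I.simulate(prog, t, steady_I_at_0)["f"]
        f2 = tight.simulate(prog, t, steady_I_at_0)["f"]
        assert np.max(np.abs(f1 - f2)) < 1e-4

    def test_trajectory_round_trips_to_dataframe(self, model_I, steady_I_at_0, tmp_path):
        t = np.linspace(0.0, 10.0, 11)
        traj = model_I.simulate(LigandProgram.constant(0.0), t, steady_I_at_0)
        wide = traj.to_wide()
        assert list(wide.columns)[0] == "t_s"
        tidy = traj.to_tidy()
        assert set(tidy.columns) == {"t_s", "channel", "value"}
        traj.write_csv(tmp_path / "traj.csv")
        assert (tmp_path / "traj.csv").exists()
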