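"""Optimal control solver and transition-energy statistics."""

import numpy as np
import pandas as pd
import pytest

import netcontrol as nc

from conftest import random_connectome, transcription_energy


def _random_problem(n, seed, **kwargs):
    rng = np.random.default_rng(seed)
    conn = random_connectome(n, seed)
    sys = nc.normalize_adjacency(conn)
    x0 = rng.standard_normal(n)
    xT = rng.standard_normal(n)
    return nc.ControlProblem(system=sys, x0=x0, xT=xT, **kwargs), conn


class TestSolveOptimalControl:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_transcription_oracle(self, seed):
        prob, _ = _random_problem(3, seed)
        traj = nc.solve_optimal_control(prob, n_steps=2000)
        oracle = transcription_energy(prob.system.a_norm, prob.x0, prob.xT, n=600)
        assert traj.total_energy == pytest.approx(oracle, rel=5e-3)

    def test_equilibrium_state_costs_nothing(self):
        conn = random_connectome(6, 4)
        sys = nc.normalize_adjacency(conn, c=0.0)
        dom = np.linalg.eigh(conn.adjacency)[1][:, -1]
        traj = nc.solve_optimal_control(
            nc.ControlProblem(system=sys, x0=dom, xT=dom)
        )
        assert traj.total_energy < 1e-10
        assert np.max(np.abs(traj.inputs)) < 1e-10

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 10.0])
    def test_degree_two_homogeneity(self, alpha):
        prob, _ = _random_problem(5, 9)
        base = nc.solve_optimal_control(prob).total_energy
        scaled = nc.ControlProblem(
            system=prob.system, x0=alpha * prob.x0, xT=alpha * prob.xT
        )
        e = nc.solve_optimal_control(scaled).total_energy
        assert e == pytest.approx(alpha**2 * base, rel=1e-6)

    def test_boundary_values_and_energy_bookkeeping(self):
        prob, _ = _random_problem(6, 2)
        traj = nc.solve_optimal_control(prob)
        np.testing.assert_array_equal(traj.states[0], prob.x0)
        assert np.linalg.norm(traj.states[-1] - prob.xT) <= 1e-6 * max(
            1.0, np.linalg.norm(prob.xT)
        )
        assert traj.total_energy == pytest.approx(traj.energy_per_node.sum())
        assert np.all(traj.energy_per_node >= 0)

    def test_raw_energy_nonincreasing_in_rho(self):
        """Higher input penalty shifts cost onto the trajectory term."""
        prob, _ = _random_problem(6, 7)
        energies = []
        for rho in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            p = nc.ControlProblem(
                system=prob.system, x0=prob.x0, xT=prob.xT, rho=rho
            )
            energies.append(nc.solve_optimal_control(p).total_energy)
        assert np.all(np.diff(energies) <= 1e-9)
        # the weighted cost component rho * E is non-decreasing
        weighted = np.array(energies) * np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
        assert np.all(np.diff(weighted) >= -1e-9)

    def test_uniform_gain_increase_reduces_energy(self):
        prob, _ = _random_problem(6, 8)
        energies = []
        for g in (0.5, 1.0, 2.0, 4.0):
            p = nc.ControlProblem(
                system=prob.system, x0=prob.x0, xT=prob.xT, b_diag=np.full(6, g)
            )
            energies.append(nc.solve_optimal_control(p).total_energy)
        assert np.all(np.diff(energies) < 0)

    def test_invalid_problems_rejected(self):
        conn = random_connectome(4, 0)
        sys = nc.normalize_adjacency(conn)
        with pytest.raises(ValueError, match="T must be positive"):
            nc.ControlProblem(system=sys, x0=np.ones(4), xT=np.ones(4), T=0)
        with pytest.raises(ValueError, match="rho"):
            nc.ControlProblem(system=sys, x0=np.ones(4), xT=np.ones(4), rho=-1)
        with pytest.raises(ValueError, match="b_diag"):
            nc.ControlProblem(
                system=sys, x0=np.ones(4), xT=np.ones(4), b_diag=np.zeros(4)
            )
        with pytest.raises(ValueError, match="n_steps"):
            prob = nc.ControlProblem(system=sys, x0=np.ones(4), xT=np.ones(4))
            nc.solve_optimal_control(prob, n_steps=10)


class TestTransitionEnergyMatrix:
    def test_identical_states_give_constant_matrix(self):
        conn = random_connectome(5, 3)
        v = np.linspace(0.2, 1.0, 5)
        states = pd.DataFrame({f"s{i}": v for i in range(4)})
        tem = nc.transition_energy_matrix(conn, states)
        assert np.ptp(tem.energies) == pytest.approx(0.0, abs=1e-9 * tem.energies[0, 0])

    def test_dominant_eigenvector_pair(self):
        conn = random_connectome(6, 5)
        v = np.linalg.eigh(conn.adjacency)[1][:, -1]
        states = pd.DataFrame({"plus": v, "minus": -v})
        tem = nc.transition_energy_matrix(conn, states)
        assert np.all(np.diag(tem.energies) < 1e-10)
        assert tem.energies[0, 1] == pytest.approx(tem.energies[1, 0], rel=1e-9)

    def test_entries_match_per_pair_solver(self):
        rng = np.random.default_rng(6)
        conn = random_connectome(5, 6)
        states = pd.DataFrame(
            rng.standard_normal((5, 4)), columns=[f"s{i}" for i in range(4)]
        )
        tem = nc.transition_energy_matrix(conn, states)
        sys = nc.normalize_adjacency(conn)
        for i in range(4):
            for j in range(4):
                traj = nc.solve_optimal_control(
                    nc.ControlProblem(
                        system=sys,
                        x0=states.iloc[:, i].to_numpy(),
                        xT=states.iloc[:, j].to_numpy(),
                    )
                )
                assert tem.energies[i, j] == pytest.approx(
                    traj.total_energy, rel=1e-8, abs=1e-12
                )

    def test_unit_norm_option(self):
        rng = np.random.default_rng(1)
        conn = random_connectome(5, 1)
        states = pd.DataFrame(rng.standard_normal((5, 3)), columns=list("abc"))
        tem = nc.transition_energy_matrix(conn, states, normalize_states=True)
        manual = states / np.linalg.norm(states, axis=0)
        tem2 = nc.transition_energy_matrix(conn, manual)
        np.testing.assert_allclose(tem.energies, tem2.energies, rtol=1e-12)

    def test_uniform_weighting_equals_plain_solver(self, small_connectome):
        rng = np.random.default_rng(2)
        states = pd.DataFrame(
            rng.standard_normal((16, 3)), columns=list("abc")
        )
        plain = nc.transition_energy_matrix(small_connectome, states)
        weighted = nc.transition_energy_matrix(
            small_connectome, states, b_diag=nc.uniform_inputs(16).b_diag
        )
        np.testing.assert_allclose(plain.energies, weighted.energies, rtol=1e-12)


class TestAsymmetry:
    def test_symmetric_matrix_has_zero_asymmetry(self):
        e = np.array([[0.0, 2, 3], [2, 0, 4], [3, 4, 0]])
        asym, net = nc.transition_asymmetry(nc.TransitionEnergyMatrix(energies=e))
        np.testing.assert_array_equal(asym, 0.0)
        np.testing.assert_array_equal(net.to_numpy(), 0.0)

    def test_two_state_closed_form(self):
        e = np.array([[0.0, 2.0], [1.0, 0.0]])
        asym, net = nc.transition_asymmetry(nc.TransitionEnergyMatrix(energies=e))
        assert asym[0, 1] == 1.0
        assert net.iloc[1] == 1.0 and net.iloc[0] == -1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_net_scores_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.random((6, 6)) * 10
        np.fill_diagonal(e, 0.0)
        asym, net = nc.transition_asymmetry(nc.TransitionEnergyMatrix(energies=e))
        assert np.allclose(asym, -asym.T)
        for j in range(6):
            brute = np.mean([e[i, j] - e[j, i] for i in range(6) if i != j])
            assert net.iloc[j] == pytest.approx(brute)


class TestSourceTargetVariability:
    def test_degenerate_constant_offdiagonal(self):
        e = np.full((4, 4), 3.0)
        np.fill_diagonal(e, 0.0)
        rep = nc.source_target_variability(nc.TransitionEnergyMatrix(energies=e))
        assert rep["degenerate"] and np.isnan(rep["t"])

    def test_column_constant_matrix_localizes_variability(self):
        # energy depends only on the target: each column constant off
        # the diagonal, so varying the source changes nothing while
        # varying the target changes everything
        e = np.tile(np.array([1.0, 5.0, 9.0, 2.0]), (4, 1))
        np.fill_diagonal(e, 0.0)
        rep = nc.source_target_variability(nc.TransitionEnergyMatrix(energies=e))
        np.testing.assert_allclose(rep["sd_across_sources"], 0.0)
        assert (rep["sd_across_targets"] > 0).all()

    def test_matches_textbook_two_sample_formulas(self):
        rng = np.random.default_rng(4)
        e = rng.random((7, 7)) * 5
        np.fill_diagonal(e, 0.0)
        rep = nc.source_target_variability(nc.TransitionEnergyMatrix(energies=e))
        from scipy.stats import ttest_ind

        t_ref = ttest_ind(
            rep["sd_across_targets"], rep["sd_across_sources"], equal_var=True
        )
        assert rep["t"] == pytest.approx(t_ref.statistic)
        assert rep["df"] == 12
        sp = np.sqrt(
            (
                rep["sd_across_targets"].var(ddof=1)
                + rep["sd_across_sources"].var(ddof=1)
            )
            / 2
        )
        d_ref = (
            rep["sd_across_targets"].mean() - rep["sd_across_sources"].mean()
        ) / sp
        assert rep["cohens_d"] == pytest.approx(d_ref)


class TestIndirectTransitions:
    def test_metric_matrix_has_no_shortcut(self):
        # distances on a line satisfy the triangle inequality
        pos = np.array([0.0, 1.0, 3.0, 7.0])
        e = np.abs(pos[:, None] - pos[None, :])
        frac, _ = nc.indirect_transition_fraction(nc.TransitionEnergyMatrix(energies=e))
        assert frac == 0.0

    def test_flagged_pair_with_best_intermediate(self):
        e = np.array([[0.0, 10, 1], [1, 0, 1], [1, 1, 0]])
        frac, table = nc.indirect_transition_fraction(
            nc.TransitionEnergyMatrix(energies=e, term_labels=list("abc"))
        )
        row = table[(table.source == "a") & (table.target == "b")].iloc[0]
        assert row.cheaper_indirect and row.best_intermediate == "c"
        assert row.best_two_step == 2.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.random((8, 8)) * 4
        np.fill_diagonal(e, 0.0)
        frac, table = nc.indirect_transition_fraction(
            nc.TransitionEnergyMatrix(energies=e)
        )
        count = 0
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                best = min(
                    e[i, k] + e[k, j] for k in range(8) if k not in (i, j)
                )
                if best < e[i, j]:
                    count += 1
        assert frac == pytest.approx(count / 56)


class TestEuclideanStateDistance:
    def test_closed_forms_and_loop_oracle(self):
        states = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0], "c": [0.0, 0.0]})
        d = nc.euclidean_state_distance(states)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "c"] == 0.0
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.standard_normal((6, 5)), columns=list("abcde"))
        d = nc.euclidean_state_distance(x)
        for i in "abcde":
            for j in "abcde":
                ref = np.linalg.norm(x[i].to_numpy() - x[j].to_numpy())
                assert d.loc[i, j] == pytest.approx(ref, abs=1e-12)
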