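"""Radial reaction–diffusion simulator: grid, scenarios, conservation."""

import numpy as np
import pytest

from liggrad import reaction_diffusion as rd
from liggrad.units import PARTICLES_PER_UM3_PER_NM


class TestGrid:
    def test_uniform_edges(self):
        g = rd.RadialGrid(10.0, 100.0, 90)
        np.testing.assert_allclose(g.edges[:10], np.arange(10.0, 20.0))
        assert g.dr == pytest.approx(1.0)

    def test_shell_volumes_sum_to_domain(self):
        g = rd.build_grid(10.0, 100.0, 137)
        total = 4 * np.pi / 3 * (100.0**3 - 10.0**3)
        assert g.volumes.sum() == pytest.approx(total, rel=1e-12)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            rd.build_grid(10.0, 100.0, 5)

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            rd.build_grid(100.0, 10.0, 50)


class TestTotalMass:
    def test_uniform_field_molecule_count(self, coarse_grid):
        st = rd.FieldState(
            time=0.0,
            L=np.full(coarse_grid.n_cells, 10.0),
            LR=np.zeros(coarse_grid.n_cells),
            R=np.zeros(coarse_grid.n_cells),
        )
        expected = (
            PARTICLES_PER_UM3_PER_NM * 10.0 * 4 * np.pi / 3 * (100.0**3 - 10.0**3)
        )
        m = rd.total_mass(st, coarse_grid)
        assert m["free"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.52e7, rel=0.01)
        assert m["bound"] == 0.0

    def test_zero_fields(self, coarse_grid):
        z = np.zeros(coarse_grid.n_cells)
        m = rd.total_mass(rd.FieldState(0.0, z, z, z), coarse_grid)
        assert all(v == 0.0 for v in m.values())

    def test_shape_mismatch_rejected(self, coarse_grid):
        z = np.zeros(coarse_grid.n_cells + 1)
        with pytest.raises(ValueError):
            rd.total_mass(rd.FieldState(0.0, z, z, z), coarse_grid)


class TestGradientMetric:
    def test_uniform_is_zero(self):
        assert rd.gradient_metric(np.full(10, 3.3)) == 0.0

    def test_two_cell_example(self):
        assert rd.gradient_metric(np.array([1.0, 3.0])) == pytest.approx(0.5)

    def test_all_zero_is_zero(self):
        assert rd.gradient_metric(np.zeros(5)) == 0.0


@pytest.fixture(scope="module")
def s1_states(coarse_grid, default_kinetics):
    cfg = rd.s1_receptor_added(coarse_grid, default_kinetics)
    t_eval = [0.0, 0.5, 2.0, 10.0, 100.0, 2000.0]
    return cfg, rd.simulate(cfg, default_kinetics, coarse_grid, t_eval)


class TestScenario1:
    def test_transient_negative_membrane_peak(self, s1_states):
        _, states = s1_states
        early = states[1]
        assert early.L[0] < early.L[-1] - 0.01  # dip at the membrane

    def test_equilibrium_is_spatially_uniform(self, s1_states):
        _, states = s1_states
        assert rd.gradient_metric(states[-1].L) < 1e-3

    def test_detailed_balance_at_equilibrium(self, s1_states, default_kinetics):
        cfg, states = s1_states
        st = states[-1]
        shell = cfg.R0 > 0
        on = default_kinetics.k_on * st.L[shell] * st.R[shell]
        off = default_kinetics.k_off * st.LR[shell]
        np.testing.assert_allclose(on, off, rtol=1e-3)

    def test_mass_conservation(self, s1_states, coarse_grid):
        _, states = s1_states
        totals = [rd.total_mass(st, coarse_grid)["total_ligand"] for st in states]
        assert np.ptp(totals) / totals[0] < 1e-3

    def test_receptor_conservation_per_cell(self, s1_states):
        _, states = s1_states
        ref = states[0].LR + states[0].R
        for st in states[1:]:
            np.testing.assert_allclose(st.LR + st.R, ref, atol=1e-6 * max(ref.max(), 1))

    def test_depletion_matches_zero_d_oracle(self, s1_states, coarse_grid,
                                             default_kinetics):
        cfg, states = s1_states
        st = states[-1]
        L_eq = float(np.sum(st.L * coarse_grid.volumes) / coarse_grid.volumes.sum())
        depletion = (10.0 - L_eq) / 10.0
        assert depletion == pytest.approx(0.10, abs=0.005)


class TestScenario2:
    def test_distant_bolus_equilibrates_homogeneously(self, coarse_grid,
                                                      default_kinetics):
        cfg = rd.s2_distant_bolus(coarse_grid, default_kinetics)
        states = rd.simulate(cfg, default_kinetics, coarse_grid,
                             [0.0, 1.0, 2000.0])
        # bolus initially confined 80-90 um from the membrane
        d = coarse_grid.centers - coarse_grid.a
        assert np.all(cfg.L0[(d < 80) | (d > 90)] == 0.0)
        assert rd.gradient_metric(states[-1].L) < 1e-3
        # transient negative peak at the membrane while receptors load
        mid = states[1]
        assert mid.L[0] < np.mean(mid.L)


class TestScenario3:
    def test_exocytosis_pulse_transient_positive_peak(self, coarse_grid,
                                                      default_kinetics):
        cfg = rd.s3_liganded_pulse(coarse_grid, default_kinetics)
        states = rd.simulate(cfg, default_kinetics, coarse_grid,
                             [0.0, 1.0, 5.0, 2000.0])
        bulk0 = states[0].L[-1]
        transient = states[1]
        assert transient.L[0] > bulk0 + 0.01  # positive membrane peak
        final = states[-1]
        assert rd.gradient_metric(final.L) < 1e-3  # peak is transient


class TestScenario4:
    def test_steady_state_matches_analytic_source_solution(self, coarse_grid,
                                                           default_kinetics):
        cfg = rd.s4_continuous_source(coarse_grid, default_kinetics, c0=10.0)
        states = rd.simulate(cfg, default_kinetics, coarse_grid,
                             [0.0, 100.0, 5000.0])
        ana = rd.s4_analytic_steady_state(coarse_grid, default_kinetics, 10.0,
                                          cfg.inner_bc[1])
        np.testing.assert_allclose(states[-1].L, ana, rtol=0.01)
        # permanent positive membrane peak
        assert states[-1].L[0] > 2.5 * 10.0

    def test_peak_is_permanent(self, coarse_grid, default_kinetics):
        cfg = rd.s4_continuous_source(coarse_grid, default_kinetics, c0=10.0)
        states = rd.simulate(cfg, default_kinetics, coarse_grid,
                             [0.0, 2000.0, 4000.0])
        assert states[-1].L[0] == pytest.approx(states[-2].L[0], rel=1e-3)
        assert rd.gradient_metric(states[-1].L) > 0.5


class TestEquilibriumDepletion:
    def test_no_receptors_no_depletion(self, coarse_grid, default_kinetics):
        assert rd.receptor_density_for_depletion(
            0.0, 10.0, default_kinetics, coarse_grid
        ) == 0.0

    def test_requested_depletion_round_trip(self, coarse_grid, default_kinetics):
        cfg = rd.s1_receptor_added(coarse_grid, default_kinetics, L0=10.0,
                                   depletion=0.10)
        got = rd.equilibrium_depletion(cfg, default_kinetics, coarse_grid)
        assert got == pytest.approx(0.10, abs=0.005)

    def test_oracle_agreement_other_receptor_load(self, coarse_grid,
                                                  default_kinetics):
        R_T = rd.receptor_density_for_depletion(0.25, 10.0, default_kinetics,
                                                coarse_grid)
        cfg = rd.s1_receptor_added(coarse_grid, default_kinetics, L0=10.0,
                                   depletion=0.25)
        np.testing.assert_allclose(cfg.R0.max(), R_T)
        got = rd.equilibrium_depletion(cfg, default_kinetics, coarse_grid)
        assert got == pytest.approx(0.25, abs=0.005)

    def test_impossible_depletion_rejected(self, coarse_grid, default_kinetics):
        with pytest.raises(ValueError):
            rd.receptor_density_for_depletion(1.0, 10.0, default_kinetics,
                                              coarse_grid)

    def test_wrong_scenario_rejected(self, coarse_grid, default_kinetics):
        cfg = rd.s4_continuous_source(coarse_grid, default_kinetics)
        with pytest.raises(ValueError):
            rd.equilibrium_depletion(cfg, default_kinetics, coarse_grid)


class TestNumerics:
    def test_grid_refinement_changes_equilibrium_little(self, default_kinetics):
        results = []
        for n in (200, 400):
            g = rd.build_grid(10.0, 100.0, n)
            cfg = rd.s1_receptor_added(g, default_kinetics, shell_thickness=0.9)
            results.append(rd.equilibrium_depletion(cfg, default_kinetics, g))
        assert abs(results[1] - results[0]) / results[0] < 0.002

    def test_invalid_t_eval_rejected(self, coarse_grid, default_kinetics):
        cfg = rd.s1_receptor_added(coarse_grid, default_kinetics)
        with pytest.raises(ValueError):
            rd.simulate(cfg, default_kinetics, coarse_grid, [1.0, 0.5])

    def test_negative_initial_field_rejected(self, coarse_grid):
        n = coarse_grid.n_cells
        with pytest.raises(ValueError):
            rd.ScenarioConfig(
                scenario="S1_receptor_added",
                L0=np.full(n, -1.0),
                LR0=np.zeros(n),
                R0=np.zeros(n),
            )

    def test_unknown_scenario_rejected(self, coarse_grid):
        n = coarse_grid.n_cells
        with pytest.raises(ValueError):
            rd.ScenarioConfig(
                scenario="S9",
                L0=np.zeros(n), LR0=np.zeros(n), R0=np.zeros(n),
            )
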