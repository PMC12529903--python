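"""Langevin integrator, minimiser, and the simulation protocols."""

import numpy as np
import pytest

from polyqcg import (BeadKind, ForceField, LangevinIntegrator, ParameterSet,
                     ProtocolSpec, build_amyloid_stack, build_beta_sheet,
                     build_chain, build_solution, default_sweep_grid,
                     largest_cluster_size, minimize, phase_sweep,
                     run_protocol, seeded_growth_protocol)
from polyqcg.constants import KB

FREE = dict(k_bond=1e-9, k_sc_bond=1e-9, k_bend=1e-9, k_torsion=1e-9,
            k_sc=1e-9, lambda_bb=1e-6, lambda_sc=1e-6, eps_hb=1e-9,
            eps_rep=1e-9, eps_hp=1e-9)


def free_particles(n=2):
    """A chain whose every interaction constant is negligible."""
    p = ParameterSet(**FREE)
    top, state = build_chain(n, p)
    return ForceField(top, p), state, p


class TestLangevinIntegrator:
    def test_ballistic_drift_without_forces_or_friction(self):
        ff, state, p = free_particles()
        integ = LangevinIntegrator(ff, state.copy(), seed=0, mode="nve")
        m = np.flatnonzero(ff.topology.is_massive)
        v = np.zeros_like(state.velocities)
        v[m] = [[0.1, -0.05, 0.02]] * len(m)
        integ.state.velocities = v
        x0 = integ.state.positions[m].copy()
        integ.run(500)
        expected = x0 + v[m] * 500 * p.dt
        np.testing.assert_allclose(integ.state.positions[m], expected,
                                   atol=1e-9)

    def test_equipartition_of_free_particles_at_300K(self):
        """Mean kinetic energy per degree of freedom of thermostatted
        free particles equals kT/2 within sampling error."""
        ff, state, p = free_particles(4)
        integ = LangevinIntegrator(ff, state.copy(), seed=7)
        integ.initialize_velocities()
        integ.run(2000)
        temps = []
        for _ in range(300):
            integ.run(120)
            temps.append(integ.kinetic_temperature())
        assert np.mean(temps) == pytest.approx(300.0, rel=0.02)

    def test_harmonic_bond_variance_matches_boltzmann(self, params):
        """Bond-length variance of a thermostatted stiff dimer equals
        k_B T / k_bond (closed-form Boltzmann variance)."""
        p = ParameterSet(**{**FREE, "k_bond": params.k_bond})
        top, state = build_chain(2, p)
        ff = ForceField(top, p)
        integ = LangevinIntegrator(ff, state.copy(), seed=11)
        integ.initialize_velocities()
        integ.run(3000)
        bb = top.indices_of(BeadKind.BB)
        samples = []
        for _ in range(4000):
            integ.run(25)
            d = np.linalg.norm(np.diff(integ.state.positions[bb], axis=0),
                               axis=1)
            samples.extend(d - p.l_bb)
        var = np.var(samples)
        assert var == pytest.approx(KB * 300.0 / p.k_bond, rel=0.15)

    def test_trajectory_bit_reproducible_under_seed(self, params):
        top, state = build_chain(5, params)

        def run_once():
            ff = ForceField(top, params)
            integ = LangevinIntegrator(ff, state.copy(), seed=99)
            integ.initialize_velocities()
            integ.run(200)
            return integ.state.positions.copy()

        np.testing.assert_array_equal(run_once(), run_once())

    def test_nve_energy_drift_small(self, params):
        """Velocity-Verlet without thermostat: drift below
        1e-3 kJ/mol/bead over 1e4 steps at dt = 0.002 ps."""
        top, state = build_beta_sheet(2, 6, "antiparallel", params)
        ff = ForceField(top, params)
        st, _ = minimize(ff, state, max_steps=300, f_tol=20.0)
        integ = LangevinIntegrator(ff, st.copy(), seed=3, mode="nve",
                                   dt=0.002, temperature=150.0)
        integ.initialize_velocities()
        integ.run(100)  # settle leapfrog half-step transient
        e0 = integ.forces().total + integ.kinetic_energy()
        integ.run(10000)
        e1 = integ.forces().total + integ.kinetic_energy()
        n_beads = int(top.is_massive.sum())
        assert abs(e1 - e0) / n_beads < 1e-3

    def test_nonfinite_coordinates_abort_with_diagnostic(self, params):
        top, state = build_chain(4, params)
        ff = ForceField(top, params)
        integ = LangevinIntegrator(ff, state.copy(), seed=0)
        integ.state.positions[0] = np.nan
        from polyqcg import SimulationError
        with pytest.raises(SimulationError):
            integ.run(2)


class TestMinimize:
    def test_stretched_bonds_relax_to_equilibrium_length(self, params):
        """Bonds initialised at 0.5 nm return to 0.38 nm."""
        top, state = build_chain(10, params)
        bb = top.indices_of(BeadKind.BB)
        st = state.copy()
        st.positions *= 0.5 / 0.38  # uniform dilation: every bond at 0.5
        ff = ForceField(top, params)
        relaxed, info = minimize(ff, st, max_steps=4000, f_tol=1.0)
        d = np.linalg.norm(np.diff(relaxed.positions[bb], axis=0), axis=1)
        assert d.mean() == pytest.approx(0.38, abs=0.001)

    def test_preminimized_state_stops_immediately(self, params):
        top, state = build_chain(5, params)
        ff = ForceField(top, params)
        st1, _ = minimize(ff, state, max_steps=2000, f_tol=5.0)
        _, info = minimize(ff, st1, max_steps=2000, f_tol=5.0)
        assert info["steps"] <= 2

    def test_monotone_energy_decrease_from_perturbed_stack(self, params,
                                                           rng):
        top, state = build_amyloid_stack(2, 2, 6, params=params)
        st = state.copy()
        m = top.is_massive
        st.positions[m] += 0.01 * rng.standard_normal((int(m.sum()), 3))
        ff = ForceField(top, params)
        e_start = ff.compute(st).total
        relaxed, info = minimize(ff, st, max_steps=300, f_tol=10.0)
        assert info["energy"] < e_start


class TestProtocols:
    def test_zero_duration_gives_initial_frame_only(self, params):
        top, state = build_chain(4, params)
        spec = ProtocolSpec(equilibration_ns=0.0, production_ns=0.0)
        traj = run_protocol(spec, top, state, params, seed=1)
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.positions(0), state.positions,
                                   atol=1e-6)

    def test_equilibration_phase_has_zero_hb_energy(self, params):
        top, state = build_beta_sheet(2, 5, "antiparallel", params)
        spec = ProtocolSpec(equilibration_ns=0.004, production_ns=0.004,
                            frame_interval_ns=0.001)
        traj = run_protocol(spec, top, state, params, seed=1)
        table = traj.energy_table()
        equil = table[table.time_ns <= 0.004]
        assert np.allclose(equil["hb"], 0.0)
        assert traj.n_frames == 9

    def test_restart_matches_continuous_run(self, params):
        # reproducibility contract: same spec + seed => same trajectory
        top, state = build_chain(5, params)
        spec = ProtocolSpec(production_ns=0.01, frame_interval_ns=0.005)
        a = run_protocol(spec, top, state, params, seed=5)
        b = run_protocol(spec, top, state, params, seed=5)
        np.testing.assert_array_equal(a.frames[-1], b.frames[-1])


class TestSweep:
    def test_default_grid_is_5x7(self):
        grid = default_sweep_grid()
        assert len(grid) == 35
        lams = sorted({g[0] for g in grid})
        epss = sorted({g[1] for g in grid})
        assert lams == [0.48, 0.53, 0.58, 0.63, 0.68]
        assert epss == [4.6, 5.6, 6.6, 7.6, 8.6, 9.6, 10.6]

    def test_dry_run_lists_cells_without_running(self, params):
        top, state = build_chain(4, params)
        table = phase_sweep(ProtocolSpec(), top, state, params,
                            dry_run=True)
        assert len(table) == 35

    def test_cells_independent_of_execution_order(self, params):
        top, state = build_solution(3, 4, 2.0e-3, seed=2, params=params)
        spec = ProtocolSpec(equilibration_ns=0.002, production_ns=0.002,
                            frame_interval_ns=0.002)
        grid = [(0.58, 6.6), (0.68, 8.6)]
        fwd = phase_sweep(spec, top, state, params, grid=grid, seed=9)
        rev = phase_sweep(spec, top, state, params, grid=grid[::-1],
                          seed=9)
        fwd = fwd.sort_values(["lambda_sc", "eps_hb"]).reset_index(drop=True)
        rev = rev.sort_values(["lambda_sc", "eps_hb"]).reset_index(drop=True)
        for col in ("n_clusters", "hbonds_per_molecule", "zipper_fraction"):
            np.testing.assert_allclose(fwd[col], rev[col])

    def test_empty_grid_rejected(self, params):
        top, state = build_chain(4, params)
        with pytest.raises(ValueError):
            phase_sweep(ProtocolSpec(), top, state, params, grid=[])


class TestSeededGrowth:
    def test_seed_only_box_keeps_sixteen_molecule_cluster(self, params):
        """The 4x4 seed alone stays one 16-molecule cluster over a short
        run (cluster contact 0.6 nm is robust to thermal motion)."""
        top, state = build_amyloid_stack(4, 4, 23, params=params)
        spec = ProtocolSpec(production_ns=0.02,
                            replenish_interval_ns=0.01,
                            frame_interval_ns=0.01)
        traj, curve = seeded_growth_protocol(spec, top, state,
                                             monomer_count=0,
                                             monomer_residues=23,
                                             params=params, seed=4)
        assert list(curve["largest_cluster"]) == [16, 16]
        assert list(curve["inserted"]) == [0, 0]

    def test_replenishment_bookkeeping_identity(self, params):
        """Inserted monomers at each checkpoint equal the dilute-phase
        deficit: target - (molecules - largest cluster)."""
        top, state = build_amyloid_stack(2, 2, 6, params=params)
        spec = ProtocolSpec(production_ns=0.01,
                            replenish_interval_ns=0.005,
                            frame_interval_ns=0.005,
                            concentration=2.0e-4)
        traj, curve = seeded_growth_protocol(spec, top, state,
                                             monomer_count=3,
                                             monomer_residues=6,
                                             params=params, seed=8)
        for _, row in curve.iterrows():
            n_before = row.n_molecules - row.inserted
            dilute = n_before - row.largest_cluster
            assert row.inserted == max(0, 3 - dilute)
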