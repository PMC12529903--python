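"""Langevin dynamics, energy minimisation, and the simulation protocols.

The integrator is a Langevin leapfrog ("sd"-style): a full-step force
kick followed by an Ornstein-Uhlenbeck friction/noise update of the
velocities and a position drift.  The friction enters through the inverse
friction coefficient τ = γ⁻¹ (ps): each particle relaxes its velocity
with decay factor exp(-dt/τ), and the matched noise amplitude
sqrt((1 - exp(-2dt/τ)) k_B T / m) makes the stationary velocity
distribution exactly Maxwellian regardless of time step for free
particles.  Only massive beads (BB, SC) are integrated; virtual sites are
re-placed from the backbone inside every force evaluation.

Protocols follow the aggregation-study structure: equilibration with
hydrogen bonds disabled, production with hydrogen bonds on; a parameter
sweep over the (λ_SC, ε_HB) grid; and seeded growth with periodic
largest-cluster measurement and monomer replenishment to hold the
dilute-phase concentration at its target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import KB, MOLAR_TO_PER_NM3
from .forcefield import ForceField
from .parameters import ParameterSet
from .topology import (BeadKind, SystemState, Topology, build_chain, merge,
                       PackingError)
from .trajectory import Trajectory

__all__ = ["SimulationError", "LangevinIntegrator", "minimize",
           "ProtocolSpec", "run_protocol", "seeded_growth_protocol",
           "default_sweep_grid", "phase_sweep"]


class SimulationError(RuntimeError):
    """Non-finite coordinates or forces encountered during integration."""


def _check_finite(arr: np.ndarray, what: str, step: int) -> None:
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0])
        raise SimulationError(
            f"non-finite {what} at step {step} (first bad bead {bad}); "
            "the system has become unstable")


class LangevinIntegrator:
    """Stochastic-dynamics integrator bound to a force field and state.

    ``mode="sd"`` is the thermostatted Langevin leapfrog; ``mode="nve"``
    is plain velocity Verlet (no friction, no noise) for energy-conservation
    checks.  Deterministic under a fixed seed.
    """

    def __init__(self, forcefield: ForceField, state: SystemState,
                 seed: int = 0, mode: str = "sd",
                 hb_enabled: bool = True,
                 temperature: float | None = None,
                 dt: float | None = None):
        if mode not in ("sd", "nve"):
            raise ValueError(f"unknown integrator mode {mode!r}")
        self.ff = forcefield
        self.state = state
        self.mode = mode
        self.hb_enabled = hb_enabled
        p = forcefield.params
        self.dt = p.dt if dt is None else float(dt)
        self.temperature = (p.temperature if temperature is None
                            else float(temperature))
        self.rng = np.random.default_rng(seed)
        top = forcefield.topology
        self._massive = np.flatnonzero(top.is_massive)
        m = top.masses(p)[self._massive]
        self._mass = m[:, None]
        a = np.exp(-self.dt / p.tau_friction)
        self._friction = a
        self._noise = np.sqrt((1.0 - a * a) * KB * self.temperature
                              / m)[:, None]
        self._last = None  # cached EnergyForces of the current positions
        self.step_count = 0

    # ------------------------------------------------------------------
    def initialize_velocities(self) -> None:
        """Draw Maxwell-Boltzmann velocities for the massive beads."""
        sigma = np.sqrt(KB * self.temperature / self._mass)
        v = np.zeros_like(self.state.velocities)
        v[self._massive] = sigma * self.rng.standard_normal(
            (self._massive.size, 3))
        self.state.velocities = v

    def forces(self):
        if self._last is None:
            self._last = self.ff.compute(self.state, self.hb_enabled)
        return self._last

    def kinetic_energy(self) -> float:
        v = self.state.velocities[self._massive]
        return float(0.5 * np.sum(self._mass * v * v))

    def kinetic_temperature(self) -> float:
        ndof = 3 * self._massive.size
        return 2.0 * self.kinetic_energy() / (ndof * KB)

    # ------------------------------------------------------------------
    def run(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self._step()

    def _step(self) -> None:
        st = self.state
        mi = self._massive
        _check_finite(st.positions[mi], "coordinate", self.step_count)
        ef = self.forces()
        _check_finite(ef.forces[mi], "force", self.step_count)
        acc = ef.forces[mi] / self._mass
        if self.mode == "sd":
            v = st.velocities[mi] + acc * self.dt
            v = self._friction * v + self._noise * \
                self.rng.standard_normal(v.shape)
            st.velocities[mi] = v
            st.positions[mi] += v * self.dt
        else:  # velocity Verlet
            v_half = st.velocities[mi] + 0.5 * acc * self.dt
            st.positions[mi] += v_half * self.dt
            self._last = None
            ef2 = self.ff.compute(st, self.hb_enabled)
            st.velocities[mi] = v_half + 0.5 * ef2.forces[mi] / \
                self._mass * self.dt
            self._last = ef2
            _check_finite(st.positions[mi], "coordinate", self.step_count)
            self.step_count += 1
            return
        self._last = None
        _check_finite(st.positions[mi], "coordinate", self.step_count)
        self.step_count += 1


# ---------------------------------------------------------------------------
# minimisation
# ---------------------------------------------------------------------------

def minimize(forcefield: ForceField, state: SystemState,
             max_steps: int = 2000, f_tol: float = 10.0,
             initial_step: float = 0.01, hb_enabled: bool = True,
             ) -> tuple[SystemState, dict]:
    """Steepest-descent energy minimisation with adaptive step length.

    Moves massive beads along the normalised force direction; the trial
    step grows by 1.2 on acceptance and shrinks by 0.2 on rejection
    (monotone energy decrease is guaranteed).  Stops when the maximum
    force component drops below ``f_tol`` (kJ/mol/nm) or after
    ``max_steps`` trials.  Returns the relaxed state and a summary dict.
    """
    st = state.copy()
    mi = np.flatnonzero(forcefield.topology.is_massive)
    ef = forcefield.compute(st, hb_enabled)
    energy = ef.total
    if not np.isfinite(energy):
        raise SimulationError("initial energy is not finite")
    h = initial_step
    n_eval = 1
    for step in range(max_steps):
        fmax = np.abs(ef.forces[mi]).max()
        if fmax < f_tol:
            break
        direction = ef.forces[mi] / fmax
        trial = st.copy()
        trial.positions[mi] += h * direction
        ef_trial = forcefield.compute(trial, hb_enabled)
        n_eval += 1
        if ef_trial.total < energy and np.isfinite(ef_trial.total):
            st, ef, energy = trial, ef_trial, ef_trial.total
            h = min(h * 1.2, 0.05)
        else:
            h *= 0.2
            if h < 1.0e-12:
                break
    return st, {"energy": energy, "max_force": float(
        np.abs(ef.forces[mi]).max()), "steps": step + 1, "n_eval": n_eval}


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class ProtocolSpec:
    """Two-phase simulation protocol with optional replenishment.

    Durations in ns; the equilibration phase runs with hydrogen bonds
    disabled, production with them enabled, following the aggregation
    protocol (500 ns equilibration / 5 μs production at full scale —
    scale down for desk-size runs).
    """

    temperature: float = 300.0       # K
    dt: float = 0.02                 # ps
    equilibration_ns: float = 0.0
    production_ns: float = 0.0
    frame_interval_ns: float = 0.1
    replenish_interval_ns: float = 100.0
    concentration: float = 1.0e-3    # mol/L, seeded-growth target
    hb_during_equilibration: bool = False
    hb_during_production: bool = True

    def replace(self, **kw) -> "ProtocolSpec":
        return dataclasses.replace(self, **kw)


def _run_phase(integ: LangevinIntegrator, duration_ns: float,
               frame_interval_ns: float, traj: Trajectory,
               t0_ns: float) -> float:
    dt_ns = integ.dt * 1.0e-3
    n_total = int(round(duration_ns / dt_ns))
    stride = max(1, int(round(frame_interval_ns / dt_ns)))
    done = 0
    while done < n_total:
        chunk = min(stride, n_total - done)
        integ.run(chunk)
        done += chunk
        ef = integ.forces()
        traj.append(t0_ns + done * dt_ns, integ.state.positions,
                    {**ef.energies, "kinetic": integ.kinetic_energy(),
                     "temperature": integ.kinetic_temperature()})
    return t0_ns + n_total * dt_ns


def run_protocol(spec: ProtocolSpec, topology: Topology, state: SystemState,
                 params: ParameterSet | None = None, seed: int = 0,
                 forcefield: ForceField | None = None) -> Trajectory:
    """Equilibrate (hydrogen bonds off), then produce (hydrogen bonds on).

    Frames and per-term energies are recorded every
    ``spec.frame_interval_ns``; the initial frame is always present.
    """
    params = (params or ParameterSet()).replace(
        temperature=spec.temperature, dt=spec.dt)
    ff = forcefield or ForceField(topology, params)
    st = state.copy()
    traj = Trajectory(box=st.box)
    integ = LangevinIntegrator(ff, st, seed=seed,
                               hb_enabled=spec.hb_during_equilibration)
    integ.initialize_velocities()
    ef = integ.forces()
    traj.append(0.0, st.positions, {**ef.energies,
                                    "kinetic": integ.kinetic_energy(),
                                    "temperature":
                                    integ.kinetic_temperature()})
    t = _run_phase(integ, spec.equilibration_ns, spec.frame_interval_ns,
                   traj, 0.0)
    integ.hb_enabled = spec.hb_during_production
    integ._last = None
    _run_phase(integ, spec.production_ns, spec.frame_interval_ns, traj, t)
    traj.events.append({"kind": "phases",
                        "equilibration_ns": spec.equilibration_ns,
                        "production_ns": spec.production_ns})
    return traj


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

def default_sweep_grid() -> list[tuple[float, float]]:
    """The published 5 × 7 grid: λ_SC 0.48-0.68 step 0.05 crossed with
    ε_HB 4.6-10.6 step 1.0 kJ/mol — 35 unique combinations."""
    lam = np.round(np.arange(0.48, 0.68 + 1e-9, 0.05), 2)
    eps = np.round(np.arange(4.6, 10.6 + 1e-9, 1.0), 1)
    return [(float(l), float(e)) for l in lam for e in eps]


def phase_sweep(spec: ProtocolSpec, topology: Topology, state: SystemState,
                params: ParameterSet | None = None,
                grid: list[tuple[float, float]] | None = None,
                seed: int = 0, analyzers=None, dry_run: bool = False):
    """Run one simulation per (λ_SC, ε_HB) grid cell and summarise each.

    Cells are independent (own seed, own copy of the system); a failing
    cell is reported in its row instead of aborting the sweep.  Returns a
    pandas DataFrame with one row per cell: the final-frame cluster count,
    hydrogen bonds per molecule and steric-zipper fraction, matching the
    phase-diagram axes.
    """
    import pandas as pd

    from .analysis import cluster_molecules, count_hbonds, zipper_fraction

    params = params or ParameterSet()
    grid = default_sweep_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("sweep grid is empty")
    if dry_run:
        return pd.DataFrame(
            [{"lambda_sc": l, "eps_hb": e} for l, e in grid])
    seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for (lam, eps), ss in zip(grid, seeds):
        cell = {"lambda_sc": lam, "eps_hb": eps}
        try:
            cell_params = params.replace(lambda_sc=lam, eps_hb=eps)
            traj = run_protocol(spec, topology, state, cell_params,
                                seed=int(ss.generate_state(1)[0] % 2**31))
            pos = traj.positions(traj.n_frames - 1)
            topology.place_virtual_sites(pos, cell_params)
            labels, _ = cluster_molecules(topology, pos, traj.box,
                                          cutoff=cell_params.r_cluster)
            hb_per_mol, _ = count_hbonds(topology, pos, traj.box,
                                         cutoff=cell_params.r_hbond)
            zf, _ = zipper_fraction(topology, pos, traj.box,
                                    params=cell_params)
            counts = np.bincount(labels)
            cell.update(n_clusters=int(labels.max() + 1),
                        largest_cluster=int(counts.max()),
                        hbonds_per_molecule=float(hb_per_mol),
                        zipper_fraction=float(zf), error="")
        except Exception as exc:  # isolate per-cell failures
            cell.update(n_clusters=np.nan, largest_cluster=np.nan,
                        hbonds_per_molecule=np.nan,
                        zipper_fraction=np.nan, error=str(exc))
        rows.append(cell)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# seeded growth
# ---------------------------------------------------------------------------

def _insert_monomers(topology: Topology, state: SystemState,
                     n_insert: int, n_residues: int, params: ParameterSet,
                     rng, min_distance: float = 1.0,
                     max_attempts: int = 2000):
    """Append extended monomers at random clash-free poses.  Returns the
    grown (topology, state) and the number actually inserted."""
    chain_top, chain_state = build_chain(n_residues, params)
    template = chain_state.positions - chain_state.positions.mean(axis=0)
    box = state.box
    existing = state.positions[topology.is_massive] % box
    parts = [(topology, state.positions)]
    inserted = 0
    tree = cKDTree(existing, boxsize=box)
    new_pts = [existing]
    for _ in range(n_insert):
        for _ in range(max_attempts):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            pos = template @ rot.T + rng.uniform(0.0, box, size=3)
            d, _ = tree.query(pos[chain_top.is_massive] % box, k=1,
                              distance_upper_bound=min_distance)
            if not np.any(np.isfinite(d)):
                parts.append((chain_top, pos))
                new_pts.append(pos[chain_top.is_massive] % box)
                tree = cKDTree(np.concatenate(new_pts), boxsize=box)
                inserted += 1
                break
        else:
            break  # insertion failure: warn upstream, continue without
    if inserted == 0:
        return topology, state, 0
    top, new_state = merge(parts, box=box)
    new_state.velocities[:len(state.velocities)] = state.velocities
    return top, new_state, inserted


def seeded_growth_protocol(spec: ProtocolSpec, seed_topology: Topology,
                           seed_state: SystemState, monomer_count: int,
                           monomer_residues: int,
                           params: ParameterSet | None = None,
                           seed: int = 0) -> tuple[Trajectory, "object"]:
    """Seeded-aggregation run with periodic replenishment.

    A preformed amyloid seed is centred in a box sized so that
    ``monomer_count`` monomers give the target molar concentration.  The
    run pauses every ``spec.replenish_interval_ns`` to measure the largest
    cluster; monomers are inserted (≥ 1 nm from any bead) to restore the
    dilute-phase count implied by the concentration.  Returns the
    trajectory and a growth-curve DataFrame (time, largest cluster,
    insertions).
    """
    import pandas as pd

    from .analysis import largest_cluster_size

    params = (params or ParameterSet()).replace(
        temperature=spec.temperature, dt=spec.dt)
    rng = np.random.default_rng(seed)
    if monomer_count > 0:
        box = (monomer_count
               / (spec.concentration * MOLAR_TO_PER_NM3)) ** (1 / 3)
    else:  # seed-only control run
        ext = seed_state.positions[seed_topology.is_massive]
        box = float(ext.max() - ext.min() + 8.0)
    target_dilute = monomer_count

    # centre the seed in the box
    seed_pos = seed_state.positions.copy()
    seed_pos += 0.5 * box - seed_pos[seed_topology.is_massive].mean(axis=0)
    top = seed_topology
    state = SystemState(seed_pos, np.zeros_like(seed_pos), box)
    top, state, n0 = _insert_monomers(top, state, monomer_count,
                                      monomer_residues, params, rng)
    if n0 < monomer_count:
        raise PackingError(f"could only place {n0}/{monomer_count} initial "
                           "monomers; lower the concentration")

    traj = Trajectory(box=box)
    rows = []
    t_ns = 0.0
    n_intervals = max(1, int(round(spec.production_ns
                                   / spec.replenish_interval_ns)))
    for interval in range(n_intervals):
        ff = ForceField(top, params)
        integ = LangevinIntegrator(ff, state, hb_enabled=True,
                                   seed=int(rng.integers(2**31)))
        integ.initialize_velocities()
        # preserve momenta of pre-existing beads across re-topologising
        t_ns = _run_phase(integ, spec.replenish_interval_ns,
                          spec.frame_interval_ns, traj, t_ns)
        state = integ.state
        largest = largest_cluster_size(top, state.positions, box,
                                       cutoff=params.r_cluster)
        dilute = top.n_molecules - largest
        n_needed = max(0, target_dilute - dilute)
        inserted = 0
        if n_needed:
            top, state, inserted = _insert_monomers(
                top, state, n_needed, monomer_residues, params, rng)
        rows.append({"time_ns": t_ns, "largest_cluster": largest,
                     "n_molecules": top.n_molecules,
                     "inserted": inserted})
        traj.events.append({"kind": "replenish", "time_ns": t_ns,
                            "largest_cluster": largest,
                            "inserted": inserted})
    return traj, pd.DataFrame(rows)
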