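"""Topology and coordinate builders for the two-bead polyglutamine model.

A polyQ_n chain carries n+2 backbone (BB) beads — one extra cap bead on
each terminus so the side-chain reference construction has both neighbours
everywhere — plus n side-chain (SC) beads, n virtual reference (Ref)
anchors, n virtual donor (HBH) sites and n-1 virtual acceptor (HBO) sites
(the acceptor of the last residue lacks its forward BB neighbours).

Builders produce idealised starting structures: extended single chains on
a planar zigzag at the β-region pseudo-bond angle, β-sheets with exact
hydrogen-bond registry (coincident HBO/HBH sites, 0.476 nm strand
spacing), amyloid stacks of interdigitated sheets, and random solutions at
a target molar concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import MOLAR_TO_PER_NM3
from .parameters import ParameterSet
from .virtual_sites import place_virtual_sites

__all__ = ["BeadKind", "Topology", "SystemState", "PackingError",
           "build_chain", "build_beta_sheet", "build_amyloid_stack",
           "build_solution", "merge"]


class BeadKind(IntEnum):
    """Bead species.  HBO/HBH/REF are virtual (massless) sites whose
    positions are functions of BB positions only."""

    BB = 0   # backbone
    SC = 1   # side chain
    HBO = 2  # hydrogen-bond acceptor (oxygen-like), virtual
    HBH = 3  # hydrogen-bond donor (hydrogen-like), virtual
    REF = 4  # side-chain reference anchor, virtual


class PackingError(RuntimeError):
    """Raised when random solution packing fails within the retry budget."""


@dataclass
class Topology:
    """Connectivity and construction records for a collection of chains.

    ``residue`` holds the residue index within the molecule (-1 for the
    terminal BB cap beads, which carry no side chain or HB sites).
    """

    kinds: np.ndarray          # (N,) int8, BeadKind values
    residue: np.ndarray        # (N,) int32, -1 for terminal caps
    molecule: np.ndarray       # (N,) int32
    bonds: np.ndarray          # (nb, 2) int32
    bond_l0: np.ndarray        # (nb,) float, nm
    bond_k: np.ndarray         # (nb,) float, kJ/mol/nm^2
    angles: np.ndarray         # (na, 3) int32, (SC, BB, Ref) restraints
    angle_theta0: np.ndarray   # (na,) float, radians
    angle_k: np.ndarray        # (na,) float, kJ/mol/rad^2
    bend_triplets: np.ndarray  # (ntr, 3) int32, consecutive BB beads
    torsion_quads: np.ndarray  # (nq, 4) int32, consecutive BB beads
    vsites: np.ndarray         # (nv,) int32, virtual bead indices
    vsite_parents: np.ndarray  # (nv, 3) int32
    vsite_coeffs: np.ndarray   # (nv, 3) float
    vsite_signs: np.ndarray    # (nv,) float, +1 HBO / -1 HBH / 0 Ref
    n_residues: np.ndarray     # (n_molecules,) int32
    sheet_id: np.ndarray | None = None  # (n_molecules,) fixture metadata

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.kinds.size

    @property
    def n_molecules(self) -> int:
        return self.n_residues.size

    @property
    def is_massive(self) -> np.ndarray:
        return (self.kinds == BeadKind.BB) | (self.kinds == BeadKind.SC)

    def indices_of(self, kind: BeadKind) -> np.ndarray:
        return np.flatnonzero(self.kinds == kind)

    def masses(self, params: ParameterSet) -> np.ndarray:
        m = np.zeros(self.n_beads)
        m[self.kinds == BeadKind.BB] = params.m_bb
        m[self.kinds == BeadKind.SC] = params.m_sc
        return m

    def vsite_labels(self) -> list[str]:
        names = {1.0: "HBO", -1.0: "HBH", 0.0: "Ref"}
        return [
            f"{names[float(s)]} of residue {self.residue[v]} "
            f"(molecule {self.molecule[v]})"
            for v, s in zip(self.vsites, self.vsite_signs)
        ]

    def place_virtual_sites(self, positions: np.ndarray,
                            params: ParameterSet) -> np.ndarray:
        """Recompute all virtual-site rows of ``positions`` in place."""
        return place_virtual_sites(
            positions, self.vsites, self.vsite_parents, self.vsite_coeffs,
            self.vsite_signs, params.l_hb, labels=self.vsite_labels())


@dataclass
class SystemState:
    """Coordinates, velocities and the periodic box of one system.

    Positions are stored unwrapped (molecules never split across the
    boundary); the minimum-image convention is applied wherever distances
    are computed.  Velocities are meaningful for massive beads only.
    """

    positions: np.ndarray  # (N, 3) nm
    velocities: np.ndarray  # (N, 3) nm/ps
    box: float             # cubic edge length, nm
    seed: int | None = None

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box, self.seed)


# ---------------------------------------------------------------------------
# single chain
# ---------------------------------------------------------------------------

def _chain_backbone(n_bb: int, params: ParameterSet) -> np.ndarray:
    """Planar zigzag backbone in the xz-plane at the bending equilibrium.

    The strand axis is x; the pleat alternates in z so that the HB-site
    normals point along ±y (the in-sheet hydrogen-bond direction) and the
    side chains along ±z (the sheet-stacking direction).
    """
    beta = 0.5 * (np.pi - np.deg2rad(params.theta_bend))
    dx = params.l_bb * np.cos(beta)
    dz = params.l_bb * np.sin(beta)
    pos = np.zeros((n_bb, 3))
    pos[:, 0] = np.arange(n_bb) * dx
    pos[1::2, 2] = dz
    return pos


def residue_period(params: ParameterSet) -> float:
    """Axial rise per residue of the ideal strand, nm."""
    beta = 0.5 * (np.pi - np.deg2rad(params.theta_bend))
    return params.l_bb * np.cos(beta)


def build_chain(n_residues: int, params: ParameterSet | None = None,
                ) -> tuple[Topology, SystemState]:
    """Build a single extended polyQ chain of ``n_residues`` glutamines.

    The smallest buildable chain has two residues (the reference-anchor
    construction needs a BB neighbour on both sides of every residue).
    """
    params = params or ParameterSet()
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2: the side-chain reference "
                         "construction needs both backbone neighbours")
    n = n_residues
    n_bb = n + 2
    # bead index layout per chain: BB caps+residues, SC, REF, HBO, HBH
    bb = np.arange(n_bb)
    sc = n_bb + np.arange(n)
    ref = n_bb + n + np.arange(n)
    hbo = n_bb + 2 * n + np.arange(n - 1)
    hbh = n_bb + 3 * n - 1 + np.arange(n)
    n_beads = n_bb + 3 * n + (n - 1)

    kinds = np.empty(n_beads, dtype=np.int8)
    kinds[bb] = BeadKind.BB
    kinds[sc] = BeadKind.SC
    kinds[ref] = BeadKind.REF
    kinds[hbo] = BeadKind.HBO
    kinds[hbh] = BeadKind.HBH

    residue = np.full(n_beads, -1, dtype=np.int32)
    residue[bb[1:-1]] = np.arange(n)
    residue[sc] = np.arange(n)
    residue[ref] = np.arange(n)
    residue[hbo] = np.arange(n - 1)
    residue[hbh] = np.arange(n)
    molecule = np.zeros(n_beads, dtype=np.int32)

    # bonds: BB-BB backbone + SC to its own BB
    bonds = np.concatenate([
        np.column_stack([bb[:-1], bb[1:]]),
        np.column_stack([sc, bb[1:-1]]),
    ]).astype(np.int32)
    bond_l0 = np.concatenate([np.full(n_bb - 1, params.l_bb),
                              np.full(n, params.l_sc)])
    bond_k = np.concatenate([np.full(n_bb - 1, params.k_bond),
                             np.full(n, params.k_sc_bond)])

    # one SC-BB-Ref restraint per residue, 180 degrees
    angles = np.column_stack([sc, bb[1:-1], ref]).astype(np.int32)
    angle_theta0 = np.full(n, np.deg2rad(params.theta_sc))
    angle_k = np.full(n, params.k_sc)

    bend_triplets = np.column_stack([bb[:-2], bb[1:-1], bb[2:]]).astype(np.int32)
    torsion_quads = (np.column_stack([bb[:-3], bb[1:-2], bb[2:-1], bb[3:]])
                     .astype(np.int32) if n_bb >= 4
                     else np.empty((0, 4), dtype=np.int32))

    # virtual-site construction records (canonical 3-parent form)
    third = 1.0 / 3.0
    vsites, parents, coeffs, signs = [], [], [], []
    for r in range(n):            # Ref_r: midpoint of BB neighbours
        vsites.append(ref[r])
        parents.append((bb[r], bb[r + 1], bb[r + 2]))
        coeffs.append((0.5, 0.0, 0.5))
        signs.append(0.0)
    for r in range(n - 1):        # HBO_r: 1/3 along bond (r, r+1), +normal
        vsites.append(hbo[r])
        parents.append((bb[r + 1], bb[r + 2], bb[r + 3]))
        coeffs.append((2.0 * third, third, 0.0))
        signs.append(1.0)
    for r in range(n):            # HBH_r: 2/3 along bond (r-1, r), -normal
        vsites.append(hbh[r])
        parents.append((bb[r], bb[r + 1], bb[r + 2]))
        coeffs.append((third, 2.0 * third, 0.0))
        signs.append(-1.0)

    top = Topology(
        kinds=kinds, residue=residue, molecule=molecule,
        bonds=bonds, bond_l0=bond_l0, bond_k=bond_k,
        angles=angles, angle_theta0=angle_theta0, angle_k=angle_k,
        bend_triplets=bend_triplets, torsion_quads=torsion_quads,
        vsites=np.array(vsites, dtype=np.int32),
        vsite_parents=np.array(parents, dtype=np.int32),
        vsite_coeffs=np.array(coeffs, dtype=float),
        vsite_signs=np.array(signs, dtype=float),
        n_residues=np.array([n], dtype=np.int32),
    )

    pos = np.zeros((n_beads, 3))
    pos[bb] = _chain_backbone(n_bb, params)
    # SC beads on the line Ref -> BB, extended by l_SC (180 degree restraint)
    refpos = 0.5 * (pos[bb[:-2]] + pos[bb[2:]])
    direction = pos[bb[1:-1]] - refpos
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    pos[sc] = pos[bb[1:-1]] + params.l_sc * direction
    top.place_virtual_sites(pos, params)

    extent = pos.max() - pos.min()
    box = float(extent + 8.0)
    state = SystemState(pos, np.zeros_like(pos), box)
    return top, state


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge(parts: list[tuple[Topology, np.ndarray]],
          box: float | None = None,
          sheet_id: np.ndarray | None = None,
          ) -> tuple[Topology, SystemState]:
    """Concatenate (topology, positions) pairs into one system."""
    off_bead = 0
    off_mol = 0
    fields = {k: [] for k in
              ("kinds", "residue", "molecule", "bonds", "bond_l0", "bond_k",
               "angles", "angle_theta0", "angle_k", "bend_triplets",
               "torsion_quads", "vsites", "vsite_parents", "vsite_coeffs",
               "vsite_signs", "n_residues", "pos")}
    for top, pos in parts:
        fields["kinds"].append(top.kinds)
        fields["residue"].append(top.residue)
        fields["molecule"].append(top.molecule + off_mol)
        fields["bonds"].append(top.bonds + off_bead)
        fields["bond_l0"].append(top.bond_l0)
        fields["bond_k"].append(top.bond_k)
        fields["angles"].append(top.angles + off_bead)
        fields["angle_theta0"].append(top.angle_theta0)
        fields["angle_k"].append(top.angle_k)
        fields["bend_triplets"].append(top.bend_triplets + off_bead)
        fields["torsion_quads"].append(top.torsion_quads + off_bead)
        fields["vsites"].append(top.vsites + off_bead)
        fields["vsite_parents"].append(top.vsite_parents + off_bead)
        fields["vsite_coeffs"].append(top.vsite_coeffs)
        fields["vsite_signs"].append(top.vsite_signs)
        fields["n_residues"].append(top.n_residues)
        fields["pos"].append(pos)
        off_bead += top.n_beads
        off_mol += top.n_molecules
    pos = np.concatenate(fields.pop("pos"))
    cat = {k: np.concatenate(v) for k, v in fields.items()}
    top = Topology(**cat, sheet_id=sheet_id)
    if box is None:
        box = float(pos.max() - pos.min() + 8.0)
    return top, SystemState(pos, np.zeros_like(pos), box)


# ---------------------------------------------------------------------------
# beta sheets
# ---------------------------------------------------------------------------

def _facing_sites(top: Topology, pos: np.ndarray, kind: BeadKind,
                  direction: float) -> np.ndarray:
    """Indices of HB sites of ``kind`` whose normal offset points along
    ±y (``direction``), for a strand lying in an xz-plane."""
    idx = top.indices_of(kind)
    y0 = np.mean(pos[top.indices_of(BeadKind.BB), 1])
    facing = (pos[idx, 1] - y0) * direction > 0
    return idx[facing]


def _registry_shift(prev_top: Topology, prev_pos: np.ndarray,
                    new_top: Topology, new_pos: np.ndarray) -> np.ndarray:
    """Translation bringing the new strand into ideal hydrogen-bond
    registry on the +y face of the previous strand.

    Tries pairings of a central acceptor (HBO) on the previous strand's
    +y face with each donor (HBH) on the new strand's -y face and keeps
    the translation that maximises the number of coincident HBO/HBH
    pairs (both families), breaking ties toward the smallest in-plane
    offset.
    """
    o_prev = _facing_sites(prev_top, prev_pos, BeadKind.HBO, +1.0)
    h_prev = _facing_sites(prev_top, prev_pos, BeadKind.HBH, +1.0)
    o_new = _facing_sites(new_top, new_pos, BeadKind.HBO, -1.0)
    h_new = _facing_sites(new_top, new_pos, BeadKind.HBH, -1.0)
    if o_prev.size == 0 or h_new.size == 0:
        raise ValueError("strand too short to establish hydrogen-bond registry")
    anchor = prev_pos[o_prev[o_prev.size // 2]]
    best = None
    for h in h_new:
        shift = anchor - new_pos[h]
        score = 0
        for a, b in ((o_prev, h_new), (h_prev, o_new)):
            if a.size and b.size:
                d = np.linalg.norm(
                    prev_pos[a][:, None, :] - (new_pos[b] + shift)[None, :, :],
                    axis=2)
                score += int(np.sum(d.min(axis=1) < 1.0e-6))
        key = (score, -abs(shift[0]))
        if best is None or key > best[0]:
            best = (key, shift)
    return best[1]


def build_beta_sheet(n_strands: int, n_residues: int,
                     arrangement: str = "antiparallel",
                     params: ParameterSet | None = None,
                     ) -> tuple[Topology, SystemState]:
    """Build an ideal β-sheet of straight strands spaced 2·l_HB apart.

    Consecutive strands are placed so that the acceptor (HBO) sites of one
    coincide with the donor (HBH) sites of the next — the ideal
    hydrogen-bond geometry, which puts the backbones 0.476 nm apart for
    the default l_HB = 0.238 nm.  In the antiparallel arrangement both HB
    families can be brought into exact registry; in the parallel
    arrangement the 1/3 vs 2/3 placement allows only one family to be
    coincident, which is what makes antiparallel sheets more stable.
    """
    params = params or ParameterSet()
    if n_strands < 1:
        raise ValueError("n_strands must be >= 1")
    if arrangement not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown arrangement {arrangement!r}")
    chain_top, chain_state = build_chain(n_residues, params)
    template = chain_state.positions
    flip = Rotation.from_euler("z", 180, degrees=True).as_matrix()

    placed: list[np.ndarray] = [template.copy()]
    for s in range(1, n_strands):
        raw = template.copy()
        if arrangement == "antiparallel" and s % 2 == 1:
            raw = raw @ flip.T
            chain_top.place_virtual_sites(raw, params)
        shift = _registry_shift(chain_top, placed[-1], chain_top, raw)
        placed.append(raw + shift)
    top, state = merge([(chain_top, p) for p in placed])
    return top, state


# ---------------------------------------------------------------------------
# amyloid stacks
# ---------------------------------------------------------------------------

def build_amyloid_stack(n_sheets: int, n_strands: int, n_residues: int,
                        intersheet_spacing: float = 0.82,
                        arrangement: str = "antiparallel",
                        params: ParameterSet | None = None,
                        ) -> tuple[Topology, SystemState]:
    """Stack β-sheets at the given spacing with interdigitated side chains.

    Adjacent sheets are offset along the strand axis so that the upward
    side chains of one sheet slot between the downward side chains of the
    next (the steric-zipper orientation).  The lateral offset is chosen
    automatically to maximise the closest approach between sheets;
    construction fails if any two beads end up closer than 0.2 nm.
    """
    params = params or ParameterSet()
    if n_sheets < 1:
        raise ValueError("n_sheets must be >= 1")
    if intersheet_spacing <= 0:
        raise ValueError("intersheet_spacing must be positive")
    sheet_top, sheet_state = build_beta_sheet(n_strands, n_residues,
                                              arrangement, params)
    if n_sheets == 1:
        sheet_top.sheet_id = np.zeros(sheet_top.n_molecules, dtype=np.int32)
        return sheet_top, sheet_state

    # candidate lateral offsets for the next sheet: half the strand
    # spacing (2 l_HB / 2) along the hydrogen-bond direction places its
    # strands over the grooves of the sheet below (steric zipper); the
    # strand-axis shifts are fallbacks.  The clash-freest offset wins.
    period = residue_period(params)
    half_strand = params.l_hb  # half of the 2 l_HB strand spacing
    candidates = [(0.0, half_strand), (0.0, -half_strand),
                  (0.5 * period, half_strand), (0.5 * period, -half_strand),
                  (0.5 * period, 0.0), (0.0, 0.0)]
    massive = sheet_top.is_massive
    base = sheet_state.positions

    placed = [base.copy()]
    prev_off = np.zeros(2)
    for k in range(1, n_sheets):
        prev_pts = placed[-1][massive]
        best = None
        for dx, dy in candidates:
            off = prev_off + (dx, dy)
            trial = base + np.array([off[0], off[1],
                                     k * intersheet_spacing])
            dmin = cKDTree(prev_pts).query(trial[massive], k=1)[0].min()
            if best is None or dmin > best[0]:
                best = (dmin, trial, off)
        placed.append(best[1])
        prev_off = best[2]

    parts = [(sheet_top, p) for p in placed]
    sheet_ids = np.repeat(np.arange(n_sheets, dtype=np.int32),
                          sheet_top.n_molecules)
    top, state = merge(parts, sheet_id=sheet_ids)
    dmin = _min_self_distance(state.positions[top.is_massive])
    if dmin < 0.2:
        raise ValueError(f"amyloid stack construction produced overlapping "
                         f"beads (closest approach {dmin:.3f} nm < 0.2 nm)")
    return top, state


def _min_self_distance(pos: np.ndarray) -> float:
    d, _ = cKDTree(pos).query(pos, k=2)
    return float(d[:, 1].min())


# ---------------------------------------------------------------------------
# random solutions
# ---------------------------------------------------------------------------

def solution_box_edge(n_chains: int, concentration: float) -> float:
    """Cubic box edge (nm) for ``n_chains`` at ``concentration`` mol/L."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    volume = n_chains / (concentration * MOLAR_TO_PER_NM3)
    return float(volume ** (1.0 / 3.0))


def build_solution(n_chains: int, n_residues: int, concentration: float,
                   seed: int, params: ParameterSet | None = None,
                   clash_cutoff: float = 0.5,
                   max_attempts: int = 100_000,
                   ) -> tuple[Topology, SystemState]:
    """Randomly distribute extended chains in a periodic box at a molar
    concentration, with no inter-chain bead pair closer than
    ``clash_cutoff`` (minimum image).  Deterministic under ``seed``."""
    params = params or ParameterSet()
    rng = np.random.default_rng(seed)
    box = solution_box_edge(n_chains, concentration)
    chain_top, chain_state = build_chain(n_residues, params)
    template = chain_state.positions - chain_state.positions.mean(axis=0)
    massive = chain_top.is_massive

    placed: list[np.ndarray] = []
    occupied: list[np.ndarray] = []
    tree = None
    for c in range(n_chains):
        for attempt in range(max_attempts):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            com = rng.uniform(0.0, box, size=3)
            pos = template @ rot.T + com
            if tree is not None:
                d, _ = tree.query(pos[massive] % box, k=1,
                                  distance_upper_bound=clash_cutoff)
                if np.any(np.isfinite(d)):
                    continue
            placed.append(pos)
            occupied.append(pos[massive] % box)
            tree = cKDTree(np.concatenate(occupied), boxsize=box)
            break
        else:
            raise PackingError(
                f"could not place chain {c + 1}/{n_chains} after "
                f"{max_attempts} attempts; lower the concentration or the "
                f"clash cutoff")
    top, state = merge([(chain_top, p) for p in placed], box=box)
    state.seed = seed
    return top, state
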