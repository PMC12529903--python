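"""Assembly of all 2BPA-Q energy terms and analytic forces.

Terms
-----
bond          stiff harmonic BB-BB and SC-BB bonds
bend          backbone pseudo-bond bending (pluggable potential)
torsion       backbone pseudo-dihedral (pluggable potential)
coupling14    optional bend-torsion coupling hook (off by default)
sc_restraint  harmonic SC-BB-Ref angle at 180 degrees
hp            shifted 8-6 pair potential over BB/SC beads
hb            switched 12/6 potential over HBO-HBH site pairs

Nonbonded exclusions: bead pairs at bond-graph distance <= 2 (1-2 and 1-3
along the backbone, a side chain with its own and the adjacent backbone
beads).  HB sites interact only through the HBO-HBH term, never HBO-HBO
or HBH-HBH, and pairs on the same or adjacent residues of one chain are
excluded to prevent self-bonding artifacts of the virtual construction.
Ref beads take part in no nonbonded interaction.

Forces on virtual sites are back-projected onto their BB parents through
the exact construction Jacobian, so the returned force array carries zero
force on virtual beads and matches the analytic gradient of the total
energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _kernels
from .neighbors import BipartiteNeighborList, NeighborList
from .parameters import ParameterSet
from .potentials import BackbonePotentials
from .topology import BeadKind, SystemState, Topology
from .virtual_sites import project_virtual_forces

__all__ = ["EnergyForces", "ForceField"]

TERMS = ("bond", "bend", "torsion", "coupling14", "sc_restraint", "hp", "hb")


@dataclass
class EnergyForces:
    """Per-term energies (kJ/mol) and per-bead forces (kJ/mol/nm)."""

    energies: dict
    forces: np.ndarray

    @property
    def total(self) -> float:
        return float(sum(self.energies.values()))


def _minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _angle_forces(pos, box, triplets, potential, forces):
    """Generic three-body angle term; returns the summed energy.

    Near-collinear configurations (sin θ → 0) get zero force, which is
    exact at a 180-degree equilibrium and standard practice otherwise.
    """
    if len(triplets) == 0:
        return 0.0
    a = _minimum_image(pos[triplets[:, 0]] - pos[triplets[:, 1]], box)
    b = _minimum_image(pos[triplets[:, 2]] - pos[triplets[:, 1]], box)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ah = a / na[:, None]
    bh = b / nb[:, None]
    cos = np.clip(np.sum(ah * bh, axis=1), -1.0, 1.0)
    theta = np.arccos(cos)
    v, dv = potential(theta)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, 0.0))
    safe = sin > 1.0e-8
    coef = np.where(safe, dv / np.where(safe, sin, 1.0), 0.0)
    fi = coef[:, None] * (bh - cos[:, None] * ah) / na[:, None]
    fk = coef[:, None] * (ah - cos[:, None] * bh) / nb[:, None]
    np.add.at(forces, triplets[:, 0], fi)
    np.add.at(forces, triplets[:, 2], fk)
    np.add.at(forces, triplets[:, 1], -(fi + fk))
    return float(np.sum(v))


def _torsion_forces(pos, box, quads, potential, forces):
    """Generic four-body proper-dihedral term; returns the summed energy."""
    if len(quads) == 0:
        return 0.0
    b1 = _minimum_image(pos[quads[:, 1]] - pos[quads[:, 0]], box)
    b2 = _minimum_image(pos[quads[:, 2]] - pos[quads[:, 1]], box)
    b3 = _minimum_image(pos[quads[:, 3]] - pos[quads[:, 2]], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(np.sum(np.cross(n1, n2) * b2, axis=1) / nb2,
                     np.sum(n1 * n2, axis=1))
    v, dv = potential(phi)
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    ok = (n1sq > 1.0e-16) & (n2sq > 1.0e-16)
    dv = np.where(ok, dv, 0.0)
    n1sq = np.where(ok, n1sq, 1.0)
    n2sq = np.where(ok, n2sq, 1.0)
    fi = (dv * nb2 / n1sq)[:, None] * n1
    fl = (-dv * nb2 / n2sq)[:, None] * n2
    t = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
    s = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
    fj = -(1.0 + t) * fi + s * fl
    fk = -(fi + fj + fl)
    np.add.at(forces, quads[:, 0], fi)
    np.add.at(forces, quads[:, 1], fj)
    np.add.at(forces, quads[:, 2], fk)
    np.add.at(forces, quads[:, 3], fl)
    return float(np.sum(v))


class ForceField:
    """Evaluator bound to one topology and parameter set.

    Owns the nonbonded neighbor lists; by default they rebuild themselves
    whenever a bead has moved more than half the skin (``auto_rebuild``
    False turns staleness into an error instead, per the engine contract).
    """

    def __init__(self, topology: Topology, params: ParameterSet | None = None,
                 backbone: BackbonePotentials | None = None,
                 box: float | None = None, auto_rebuild: bool = True):
        self.topology = topology
        self.params = params or ParameterSet()
        self.backbone = backbone or BackbonePotentials.default(self.params)
        self.auto_rebuild = auto_rebuild
        self._box = box
        self._hp_list: NeighborList | None = None
        self._hb_list: BipartiteNeighborList | None = None
        self._prepare()

    # ------------------------------------------------------------------
    def _prepare(self) -> None:
        top, p = self.topology, self.params
        self._massive = top.is_massive
        active = np.flatnonzero(self._massive)
        lam = np.where(top.kinds[active] == BeadKind.BB,
                       p.lambda_bb, p.lambda_sc)
        self._hp_indices = active
        self._lam = lam
        lam_full = np.zeros(top.n_beads)
        lam_full[active] = lam
        self._lam_full = lam_full

        # bonded-graph exclusions at distance <= 2
        g = nx.Graph()
        g.add_nodes_from(range(top.n_beads))
        g.add_edges_from(map(tuple, top.bonds))
        excl = set()
        n = top.n_beads
        for i in active:
            near = nx.single_source_shortest_path_length(g, int(i), cutoff=2)
            for j in near:
                if j > i and self._massive[j]:
                    excl.add(int(i) * n + int(j))
        self._hp_exclusions = np.array(sorted(excl), dtype=np.int64)

        # HB-pair exclusions: same or adjacent residue on the same chain
        hbo = top.indices_of(BeadKind.HBO)
        hbh = top.indices_of(BeadKind.HBH)
        self._hbo, self._hbh = hbo, hbh
        excl_hb = []
        same = (top.molecule[hbo][:, None] == top.molecule[hbh][None, :])
        close = (np.abs(top.residue[hbo][:, None]
                        - top.residue[hbh][None, :]) <= 1)
        for a, b in zip(*np.nonzero(same & close)):
            excl_hb.append(int(hbo[a]) * n + int(hbh[b]))
        self._hb_exclusions = np.array(sorted(excl_hb), dtype=np.int64)

    def _lists(self, box: float):
        p = self.params
        if self._hp_list is None or self._hp_list.box != box:
            self._hp_list = NeighborList(self._hp_indices, p.cutoff, p.skin,
                                         box, self._hp_exclusions)
            self._hb_list = BipartiteNeighborList(
                self._hbo, self._hbh, p.sigma_hb, p.skin, box,
                self._hb_exclusions)
        return self._hp_list, self._hb_list

    # ------------------------------------------------------------------
    def compute(self, state: SystemState, hb_enabled: bool = True,
                ) -> EnergyForces:
        """Place virtual sites, evaluate every term, project virtual
        forces back onto the backbone."""
        top, p = self.topology, self.params
        pos = state.positions
        box = state.box
        top.place_virtual_sites(pos, p)
        forces = np.zeros_like(pos)
        e = dict.fromkeys(TERMS, 0.0)

        e["bond"] = float(_kernels.bond_kernel(
            pos, box, top.bonds[:, 0].astype(np.int64),
            top.bonds[:, 1].astype(np.int64),
            top.bond_l0, top.bond_k, forces))
        if self.backbone.bend is not None:
            e["bend"] = _angle_forces(pos, box, top.bend_triplets,
                                      self.backbone.bend, forces)
        if self.backbone.torsion is not None:
            e["torsion"] = _torsion_forces(pos, box, top.torsion_quads,
                                           self.backbone.torsion, forces)
        if self.backbone.coupling14 is not None:
            e["coupling14"] = self.backbone.coupling14(
                pos, box, top, forces)

        def _sc_pot(theta, theta0=top.angle_theta0, k=top.angle_k):
            d = theta - theta0
            return 0.5 * k * d * d, k * d

        e["sc_restraint"] = _angle_forces(pos, box, top.angles, _sc_pot,
                                          forces)

        hp_list, hb_list = self._lists(box)
        hp_list.ensure_current(pos, self.auto_rebuild)
        eps_pair = (p.eps_hp * (self._lam_full[hp_list.pairs_i]
                                * self._lam_full[hp_list.pairs_j]) ** p.alpha)
        e["hp"] = float(_kernels.hp_pair_kernel(
            pos, box, hp_list.pairs_i, hp_list.pairs_j, eps_pair,
            p.sigma, p.eps_rep, p.cutoff, forces))

        if hb_enabled and self._hbo.size and self._hbh.size:
            hb_list.ensure_current(pos, self.auto_rebuild)
            e["hb"] = float(_kernels.hb_pair_kernel(
                pos, box, hb_list.pairs_i, hb_list.pairs_j,
                p.eps_hb, p.sigma_hb, forces))

        project_virtual_forces(forces, pos, top.vsites, top.vsite_parents,
                               top.vsite_coeffs, top.vsite_signs, p.l_hb)
        return EnergyForces(e, forces)
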