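"""Coordinate file input/output (GRO and PDB dialects via MDAnalysis).

GRO is the canonical format (nm units match the internal unit system);
PDB (Å) is provided for visualisation interoperability.  Bead kinds map
to atom names BB / SC / OV (acceptor) / HV (donor) / RF (reference); all
residues are written as GLN with one residue id per molecule.  Virtual
beads are written so analyses can run on files alone; a reader finding no
HB sites can rebuild them from the backbone.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .parameters import ParameterSet
from .topology import BeadKind, SystemState, Topology, build_chain, merge

__all__ = ["KindMappingError", "ATOM_NAMES", "write_structure",
           "read_structure", "topology_from_kinds"]

#: bead kind -> file atom name
ATOM_NAMES = {BeadKind.BB: "BB", BeadKind.SC: "SC", BeadKind.HBO: "OV",
              BeadKind.HBH: "HV", BeadKind.REF: "RF"}
_NAME_TO_KIND = {v: k for k, v in ATOM_NAMES.items()}


class KindMappingError(ValueError):
    """An atom name in a coordinate file does not map to a bead kind."""


def _universe(topology: Topology, positions: np.ndarray, box: float,
              title: str):
    import MDAnalysis as mda

    n = topology.n_beads
    n_mol = topology.n_molecules
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=n, n_residues=n_mol, n_segments=1,
                               atom_resindex=topology.molecule,
                               trajectory=True)
        u.add_TopologyAttr("names",
                           [ATOM_NAMES[BeadKind(k)] for k in topology.kinds])
        u.add_TopologyAttr("resnames", ["GLN"] * n_mol)
        u.add_TopologyAttr("resids", np.arange(1, n_mol + 1))
        u.add_TopologyAttr("elements", ["C"] * n)
    u.atoms.positions = np.asarray(positions, dtype=np.float32) * 10.0  # nm->Å
    u.dimensions = [box * 10.0] * 3 + [90.0] * 3
    return u


def write_structure(path: str | Path, topology: Topology,
                    state: SystemState, title: str = "") -> None:
    """Write a GRO or PDB file (chosen by extension) in the canonical
    bead order.  ``title`` lands in the file header."""
    path = Path(path)
    u = _universe(topology, state.positions, state.box, title)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".gro":
            u.atoms.write(str(path))
        elif path.suffix.lower() == ".pdb":
            u.atoms.write(str(path), remarks=title)
        else:
            raise ValueError(f"unsupported structure format {path.suffix!r}")
    if title and path.suffix.lower() == ".gro":
        lines = path.read_text().splitlines()
        lines[0] = title
        path.write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path,
                   params: ParameterSet | None = None,
                   ) -> tuple[Topology, SystemState]:
    """Read a GRO/PDB file written in the canonical bead layout.

    The topology is rebuilt from the per-molecule backbone count; bead
    kinds are recovered from atom names.  Missing virtual sites are
    recomputed from the backbone.  Files with unrecognised atom names
    raise :class:`KindMappingError` naming the offending atom.
    """
    import MDAnalysis as mda

    params = params or ParameterSet()
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    names = u.atoms.names
    for i, name in enumerate(names):
        if name not in _NAME_TO_KIND:
            raise KindMappingError(
                f"{path.name}: atom {i + 1} has name {name!r}; expected one "
                f"of {sorted(_NAME_TO_KIND)} (BB/SC beads and OV/HV/RF "
                "virtual sites)")
    kinds = np.array([_NAME_TO_KIND[n] for n in names], dtype=np.int8)
    molecule = u.atoms.resindices.astype(np.int32)
    pos = u.atoms.positions.astype(float) / 10.0  # Å -> nm
    box = float(u.dimensions[0]) / 10.0 if u.dimensions is not None \
        else float(pos.max() - pos.min() + 8.0)
    top, state = topology_from_kinds(kinds, molecule, pos, box, params)
    return top, state


def topology_from_kinds(kinds: np.ndarray, molecule: np.ndarray,
                        positions: np.ndarray, box: float,
                        params: ParameterSet,
                        ) -> tuple[Topology, SystemState]:
    """Rebuild a full topology from per-bead kinds and molecule ids.

    Assumes each molecule follows the canonical layout (all BB beads in
    backbone order, then SC, Ref, HBO, HBH in residue order — the order
    this package writes).  Virtual-site coordinates are recomputed when
    the file carried none.
    """
    parts = []
    has_sites = np.any(kinds == BeadKind.HBO)
    for m in np.unique(molecule):
        sel = molecule == m
        n_bb = int(np.sum(kinds[sel] == BeadKind.BB))
        n_sc = int(np.sum(kinds[sel] == BeadKind.SC))
        if n_bb != n_sc + 2:
            raise KindMappingError(
                f"molecule {m}: {n_bb} backbone beads with {n_sc} side "
                "chains does not match the two-cap chain layout")
        top_m, state_m = build_chain(n_sc, params)
        pos_m = state_m.positions
        src = positions[sel]
        if has_sites:
            if src.shape != pos_m.shape:
                raise KindMappingError(
                    f"molecule {m}: bead count {len(src)} does not match "
                    f"the canonical layout ({len(pos_m)})")
            pos_m = src.copy()
        else:  # only massive beads present: rebuild the virtual sites
            mass_rows = top_m.is_massive
            if int(mass_rows.sum()) != len(src):
                raise KindMappingError(
                    f"molecule {m}: massive bead count mismatch")
            pos_m[mass_rows] = src
            top_m.place_virtual_sites(pos_m, params)
        parts.append((top_m, pos_m))
    return merge(parts, box=box)
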