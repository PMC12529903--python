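"""Aggregation and structural analyses.

Three observables characterise aggregation state, all pure functions of a
single frame:

* **clustering** — two molecules belong to one cluster when any of their
  BB or SC beads are within 0.6 nm (minimum image); clusters are the
  connected components of that molecule graph.
* **hydrogen bonding** — contacts between donor (HBH) and acceptor (HBO)
  sites within 0.12 nm, intra- and intermolecular, normalised per
  molecule.  Each residue can form at most two bonds (one per site).
* **steric zipper** — a residue pair is in zipper conformation when the
  closest of its four BB/SC bead distances lies in [0.38, 0.5] nm
  (proximity) and the farthest in [1.2, 2.5] nm (side chains aligned the
  same way); the fraction of flagged residues is reported.

Structural helpers: per-molecule radius of gyration (unwrapped,
mass-weighted), the R_g-vs-length scaling exponent, mid-plane intersheet
spacing, and largest-cluster growth curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .parameters import ParameterSet
from .topology import BeadKind, Topology

__all__ = ["AnalysisReport", "cluster_molecules", "largest_cluster_size",
           "count_hbonds", "hbond_counts_per_residue", "zipper_fraction",
           "radius_of_gyration", "fit_scaling_exponent",
           "intersheet_spacing", "assign_sheets", "growth_curve",
           "average_growth_curves", "analyze_frame"]


def _pairs_within(pos: np.ndarray, box: float, cutoff: float) -> np.ndarray:
    """(n, 2) index pairs within cutoff under the minimum image."""
    if len(pos) == 0:
        return np.empty((0, 2), dtype=np.int64)
    if box > 2.0 * cutoff:
        wrapped = pos % box
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
        return tree.query_pairs(cutoff, output_type="ndarray")
    delta = pos[:, None, :] - pos[None, :, :]
    delta -= box * np.round(delta / box)
    d2 = np.sum(delta * delta, axis=2)
    ii, jj = np.triu_indices(len(pos), k=1)
    keep = d2[ii, jj] <= cutoff * cutoff
    return np.column_stack([ii[keep], jj[keep]])


def _mi_dist(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    d = a - b
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_molecules(topology: Topology, positions: np.ndarray,
                      box: float, cutoff: float = 0.6,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Cluster labels (per molecule) and cluster sizes (molecules).

    Only massive (BB, SC) beads define contacts.  Labels are contiguous
    integers starting at 0; sizes are ordered by label.
    """
    if topology.n_beads == 0 or len(positions) == 0:
        raise ValueError("cannot cluster an empty frame")
    beads = np.flatnonzero(topology.is_massive)
    mol = topology.molecule[beads]
    pairs = _pairs_within(positions[beads], box, cutoff)
    n_mol = topology.n_molecules
    if len(pairs):
        mi = mol[pairs[:, 0]]
        mj = mol[pairs[:, 1]]
        keep = mi != mj
        data = np.ones(keep.sum(), dtype=np.int8)
        adj = sparse.coo_matrix((data, (mi[keep], mj[keep])),
                                shape=(n_mol, n_mol))
    else:
        adj = sparse.coo_matrix((n_mol, n_mol))
    n_comp, labels = sparse.csgraph.connected_components(adj,
                                                         directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return labels, sizes


def largest_cluster_size(topology: Topology, positions: np.ndarray,
                         box: float, cutoff: float = 0.6) -> int:
    _, sizes = cluster_molecules(topology, positions, box, cutoff)
    return int(sizes.max())


# ---------------------------------------------------------------------------
# hydrogen bonding
# ---------------------------------------------------------------------------

def count_hbonds(topology: Topology, positions: np.ndarray, box: float,
                 cutoff: float = 0.12) -> tuple[float, np.ndarray]:
    """Average hydrogen bonds per molecule and the (HBO, HBH) pair list.

    Counts HBO-HBH site pairs within ``cutoff`` (nm), intra- and
    intermolecular alike.
    """
    hbo = topology.indices_of(BeadKind.HBO)
    hbh = topology.indices_of(BeadKind.HBH)
    if hbo.size == 0 or hbh.size == 0:
        raise ValueError("frame has no hydrogen-bonding sites; the "
                         "topology lacks HBO/HBH records")
    if box > 2.0 * cutoff:
        po = positions[hbo] % box
        ph = positions[hbh] % box
        po[po >= box] = 0.0
        ph[ph >= box] = 0.0
        hits = cKDTree(po, boxsize=box).query_ball_tree(
            cKDTree(ph, boxsize=box), cutoff)
        pairs = np.array([(hbo[i], hbh[j]) for i, lst in enumerate(hits)
                          for j in lst], dtype=np.int64).reshape(-1, 2)
    else:
        d = _mi_dist(positions[hbo][:, None, :], positions[hbh][None, :, :],
                     box)
        ii, jj = np.nonzero(d <= cutoff)
        pairs = np.column_stack([hbo[ii], hbh[jj]])
    return len(pairs) / topology.n_molecules, pairs


def hbond_counts_per_residue(topology: Topology, positions: np.ndarray,
                             box: float, cutoff: float = 0.12) -> np.ndarray:
    """(n_molecules, max_residues) array of per-residue bond counts.

    A residue participates through its HBO and its HBH site, so the count
    is bounded by two.
    """
    _, pairs = count_hbonds(topology, positions, box, cutoff)
    counts = np.zeros((topology.n_molecules,
                       int(topology.n_residues.max())), dtype=int)
    for bead in pairs.ravel():
        counts[topology.molecule[bead], topology.residue[bead]] += 1
    return counts


# ---------------------------------------------------------------------------
# steric zipper
# ---------------------------------------------------------------------------

def _residue_tables(topology: Topology):
    bb = np.flatnonzero((topology.kinds == BeadKind.BB)
                        & (topology.residue >= 0))
    sc = topology.indices_of(BeadKind.SC)
    order_bb = np.lexsort((topology.residue[bb], topology.molecule[bb]))
    order_sc = np.lexsort((topology.residue[sc], topology.molecule[sc]))
    bb = bb[order_bb]
    sc = sc[order_sc]
    assert np.array_equal(topology.molecule[bb], topology.molecule[sc])
    return bb, sc


def zipper_fraction(topology: Topology, positions: np.ndarray, box: float,
                    params: ParameterSet | None = None,
                    mode: str = "all",
                    ) -> tuple[float, np.ndarray]:
    """Fraction of residues in steric-zipper conformation, plus flags.

    ``mode="all"`` takes the min/max over all four inter-residue bead
    pairs {BB-BB, BB-SC, SC-BB, SC-SC}; ``mode="mixed"`` restricts to the
    mixed-kind pairs.  Residue pairs closer than three residues along one
    chain are excluded.
    """
    if mode not in ("all", "mixed"):
        raise ValueError(f"unknown zipper mode {mode!r}")
    p = params or ParameterSet()
    lo_min, hi_min = p.zipper_min
    lo_max, hi_max = p.zipper_max
    bb, sc = _residue_tables(topology)
    n_res = bb.size
    flags = np.zeros(n_res, dtype=bool)
    # candidates: residue pairs whose BB beads could satisfy the proximity
    # window once side chains (up to 2 l_SC away) are considered
    candidate_r = hi_min + 2.0 * p.l_sc + 0.2
    cand = _pairs_within(positions[bb], box, candidate_r)
    if len(cand):
        a, b = cand[:, 0], cand[:, 1]
        same_chain = topology.molecule[bb[a]] == topology.molecule[bb[b]]
        res_sep = np.abs(topology.residue[bb[a]] - topology.residue[bb[b]])
        keep = ~(same_chain & (res_sep < 3))
        a, b = a[keep], b[keep]
        if mode == "all":
            combos = ((bb, bb), (bb, sc), (sc, bb), (sc, sc))
        else:
            combos = ((bb, sc), (sc, bb))
        d = np.stack([_mi_dist(positions[x[a]], positions[y[b]], box)
                      for x, y in combos])
        dmin = d.min(axis=0)
        dmax = d.max(axis=0)
        hit = ((dmin >= lo_min) & (dmin <= hi_min)
               & (dmax >= lo_max) & (dmax <= hi_max))
        flags[a[hit]] = True
        flags[b[hit]] = True
    return float(flags.mean()) if n_res else 0.0, flags


# ---------------------------------------------------------------------------
# radius of gyration and scaling
# ---------------------------------------------------------------------------

def _unwrap_molecule(topology: Topology, positions: np.ndarray, box: float,
                     beads: np.ndarray) -> np.ndarray:
    """Unwrap one molecule across periodic boundaries by walking its bonds."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(beads.tolist())
    sel = np.isin(topology.bonds[:, 0], beads) \
        & np.isin(topology.bonds[:, 1], beads)
    g.add_edges_from(map(tuple, topology.bonds[sel]))
    out = {}
    root = int(beads[0])
    out[root] = positions[root].copy()
    for u, v in nx.bfs_edges(g, root):
        d = positions[v] - positions[u]
        d -= box * np.round(d / box)
        out[v] = out[u] + d
    return np.array([out[int(b)] for b in beads])


def radius_of_gyration(topology: Topology, positions: np.ndarray,
                       box: float, params: ParameterSet | None = None,
                       ) -> np.ndarray:
    """Mass-weighted R_g (nm) of each molecule over its BB and SC beads.

    Molecules are unwrapped across periodic boundaries first; a residual
    bond longer than 0.6 nm after unwrapping indicates a broken frame and
    raises.
    """
    p = params or ParameterSet()
    masses = topology.masses(p)
    out = np.empty(topology.n_molecules)
    for m in range(topology.n_molecules):
        beads = np.flatnonzero((topology.molecule == m)
                               & topology.is_massive)
        pos = _unwrap_molecule(topology, positions, box, beads)
        sel = np.isin(topology.bonds[:, 0], beads)
        lookup = {int(b): k for k, b in enumerate(beads)}
        for i, j in topology.bonds[sel]:
            d = np.linalg.norm(pos[lookup[int(i)]] - pos[lookup[int(j)]])
            if d > 0.6:
                raise ValueError(
                    f"bond {i}-{j} is {d:.2f} nm after unwrapping: frame "
                    "has wrap artifacts or a broken molecule")
        w = masses[beads]
        com = np.average(pos, axis=0, weights=w)
        out[m] = np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1),
                                    weights=w))
    return out


def fit_scaling_exponent(lengths, rg_values) -> tuple[float, float]:
    """Least-squares slope of log R_g vs log N, with its standard error.

    The apparent exponent ν diagnoses solvent quality: ν ≈ 0.5 for an
    ideal chain, 0.588 for good solvent, 1/3 for a collapsed globule.
    """
    lengths = np.asarray(lengths, dtype=float)
    rg_values = np.asarray(rg_values, dtype=float)
    if lengths.size < 3:
        raise ValueError("need at least 3 chain lengths")
    if np.any(lengths <= 0) or np.any(rg_values <= 0):
        raise ValueError("lengths and R_g values must be positive")
    fit = linregress(np.log(lengths), np.log(rg_values))
    return float(fit.slope), float(fit.stderr)


# ---------------------------------------------------------------------------
# sheets
# ---------------------------------------------------------------------------

def assign_sheets(topology: Topology, positions: np.ndarray, box: float,
                  cutoff: float = 0.12, min_bonds: int = 2) -> np.ndarray:
    """Per-molecule sheet labels from hydrogen-bond connectivity.

    Molecules sharing at least ``min_bonds`` intermolecular hydrogen
    bonds are strands of one sheet (connected components).  Falls back to
    the builder's fixture metadata when the topology carries it.
    """
    if topology.sheet_id is not None:
        return topology.sheet_id
    _, pairs = count_hbonds(topology, positions, box, cutoff)
    n = topology.n_molecules
    counts = {}
    for o, h in pairs:
        a, b = sorted((int(topology.molecule[o]), int(topology.molecule[h])))
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    rows = [k for k, v in counts.items() if v >= min_bonds]
    if rows:
        ij = np.array(rows)
        adj = sparse.coo_matrix((np.ones(len(ij)), (ij[:, 0], ij[:, 1])),
                                shape=(n, n))
    else:
        adj = sparse.coo_matrix((n, n))
    _, labels = sparse.csgraph.connected_components(adj, directed=False)
    return labels


def intersheet_spacing(topology: Topology, positions: np.ndarray,
                       box: float, sheet_labels: np.ndarray | None = None,
                       ) -> float:
    """Mean distance (nm) between adjacent β-sheet mid-planes.

    A plane is fitted (total least squares) to each sheet's BB beads; the
    sheet centroids are projected onto the average normal, sorted, and
    the mean adjacent gap returned.
    """
    labels = (sheet_labels if sheet_labels is not None
              else assign_sheets(topology, positions, box))
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 sheets to measure a spacing")
    bb = np.flatnonzero(topology.kinds == BeadKind.BB)
    normals, centroids = [], []
    for s in uniq:
        beads = bb[np.isin(topology.molecule[bb],
                           np.flatnonzero(labels == s))]
        pts = positions[beads]
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        normals.append(vt[2])
        centroids.append(c)
    normals = np.array(normals)
    ref = normals[0]
    normals[np.sum(normals * ref, axis=1) < 0] *= -1
    n_mean = normals.mean(axis=0)
    n_mean /= np.linalg.norm(n_mean)
    proj = np.sort(np.array(centroids) @ n_mean)
    return float(np.mean(np.diff(proj)))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def growth_curve(trajectory, topology: Topology, cutoff: float = 0.6):
    """Largest-cluster size (molecules) versus time for a fixed-topology
    trajectory.  Returns a pandas DataFrame (time_ns, largest_cluster)."""
    import pandas as pd

    rows = []
    for k in range(trajectory.n_frames):
        pos = trajectory.positions(k)
        rows.append({"time_ns": trajectory.times[k],
                     "largest_cluster": largest_cluster_size(
                         topology, pos, trajectory.box, cutoff)})
    return pd.DataFrame(rows)


def average_growth_curves(curves):
    """Average replica growth curves on their common time axis."""
    import pandas as pd

    merged = pd.concat(curves).groupby("time_ns", as_index=False).mean()
    return merged


# ---------------------------------------------------------------------------
# frame report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Summary of one frame."""

    n_clusters: int
    largest_cluster: int
    hbonds_per_molecule: float
    zipper_fraction: float
    rg_mean: float
    intersheet_spacing: float | None = None


def analyze_frame(topology: Topology, positions: np.ndarray, box: float,
                  params: ParameterSet | None = None,
                  with_spacing: bool = False) -> AnalysisReport:
    p = params or ParameterSet()
    topology.place_virtual_sites(positions, p)
    labels, sizes = cluster_molecules(topology, positions, box, p.r_cluster)
    hb, _ = count_hbonds(topology, positions, box, p.r_hbond)
    zf, _ = zipper_fraction(topology, positions, box, p)
    rg = radius_of_gyration(topology, positions, box, p)
    spacing = None
    if with_spacing:
        try:
            spacing = intersheet_spacing(topology, positions, box)
        except ValueError:
            spacing = None
    return AnalysisReport(
        n_clusters=int(sizes.size), largest_cluster=int(sizes.max()),
        hbonds_per_molecule=float(hb), zipper_fraction=float(zf),
        rg_mean=float(rg.mean()), intersheet_spacing=spacing)
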