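"""Verlet neighbor lists built on periodic k-d trees.

Candidate pair lists are rebuilt whenever any tracked bead has moved more
than half the skin since the last build, which guarantees that no pair
inside the true interaction cutoff is ever missed between rebuilds.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["StaleNeighborListError", "NeighborList", "BipartiteNeighborList"]


class StaleNeighborListError(RuntimeError):
    """A tracked bead moved beyond the skin since the last rebuild while
    automatic rebuilding was disabled."""


def _wrap(pos: np.ndarray, box: float) -> np.ndarray:
    w = pos % box
    # guard against w == box from floating-point roundoff
    w[w >= box] = 0.0
    return w


class _TrackerMixin:
    def displacement_exceeded(self, positions: np.ndarray) -> bool:
        if self._ref is None:
            return True
        disp = positions[self._tracked] - self._ref
        return bool(np.any(np.sum(disp * disp, axis=1)
                           > (0.5 * self.skin) ** 2))

    def ensure_current(self, positions: np.ndarray,
                       auto_rebuild: bool = True) -> bool:
        """Rebuild if stale.  Returns True when a rebuild happened.
        The initial build always happens regardless of the policy."""
        if self._ref is None:
            self.rebuild(positions)
            return True
        if self.displacement_exceeded(positions):
            if not auto_rebuild:
                raise StaleNeighborListError(
                    "a bead moved beyond half the neighbor-list skin since "
                    "the last rebuild")
            self.rebuild(positions)
            return True
        return False


class NeighborList(_TrackerMixin):
    """Half pair list over one set of beads within cutoff + skin."""

    def __init__(self, indices: np.ndarray, cutoff: float, skin: float,
                 box: float, exclusions: np.ndarray | None = None):
        self.indices = np.asarray(indices, dtype=np.int64)
        self.cutoff = float(cutoff)
        self.skin = float(skin)
        self.box = float(box)
        self._tracked = self.indices
        self._ref = None
        self._excl = (np.sort(exclusions) if exclusions is not None
                      else np.empty(0, dtype=np.int64))
        self.pairs_i = np.empty(0, dtype=np.int64)
        self.pairs_j = np.empty(0, dtype=np.int64)

    def rebuild(self, positions: np.ndarray) -> None:
        pts = positions[self.indices]
        r = self.cutoff + self.skin
        if self.box > 2.0 * r:
            tree = cKDTree(_wrap(pts.copy(), self.box), boxsize=self.box)
            pairs = tree.query_pairs(r, output_type="ndarray")
        else:  # box too small for the periodic tree: brute force
            delta = pts[:, None, :] - pts[None, :, :]
            delta -= self.box * np.round(delta / self.box)
            d2 = np.sum(delta * delta, axis=2)
            ii, jj = np.triu_indices(len(pts), k=1)
            keep = d2[ii, jj] < r * r
            pairs = np.column_stack([ii[keep], jj[keep]])
        gi = self.indices[pairs[:, 0]] if len(pairs) else np.empty(0, np.int64)
        gj = self.indices[pairs[:, 1]] if len(pairs) else np.empty(0, np.int64)
        lo = np.minimum(gi, gj)
        hi = np.maximum(gi, gj)
        if self._excl.size and lo.size:
            code = lo * positions.shape[0] + hi
            keep = ~np.isin(code, self._excl)
            lo, hi = lo[keep], hi[keep]
        self.pairs_i, self.pairs_j = lo, hi
        self._ref = positions[self._tracked].copy()

    def all_pairs_reference(self, positions: np.ndarray) -> set[tuple]:
        """Brute-force pair set within the true cutoff (oracle for tests)."""
        pts = positions[self.indices]
        delta = pts[:, None, :] - pts[None, :, :]
        delta -= self.box * np.round(delta / self.box)
        d2 = np.sum(delta * delta, axis=2)
        ii, jj = np.triu_indices(len(pts), k=1)
        keep = d2[ii, jj] < self.cutoff ** 2
        out = set()
        excl = set(self._excl.tolist())
        for a, b in zip(self.indices[ii[keep]], self.indices[jj[keep]]):
            lo, hi = (int(a), int(b)) if a < b else (int(b), int(a))
            if lo * positions.shape[0] + hi in excl:
                continue
            out.add((lo, hi))
        return out


class BipartiteNeighborList(_TrackerMixin):
    """Pair list between two disjoint bead sets (HBO vs HBH sites)."""

    def __init__(self, indices_a: np.ndarray, indices_b: np.ndarray,
                 cutoff: float, skin: float, box: float,
                 exclusions: np.ndarray | None = None):
        self.indices_a = np.asarray(indices_a, dtype=np.int64)
        self.indices_b = np.asarray(indices_b, dtype=np.int64)
        self.cutoff = float(cutoff)
        self.skin = float(skin)
        self.box = float(box)
        self._tracked = np.concatenate([self.indices_a, self.indices_b])
        self._ref = None
        self._excl = (np.sort(exclusions) if exclusions is not None
                      else np.empty(0, dtype=np.int64))
        self.pairs_i = np.empty(0, dtype=np.int64)
        self.pairs_j = np.empty(0, dtype=np.int64)

    def rebuild(self, positions: np.ndarray) -> None:
        r = self.cutoff + self.skin
        pa = positions[self.indices_a]
        pb = positions[self.indices_b]
        if self.box > 2.0 * r:
            ta = cKDTree(_wrap(pa.copy(), self.box), boxsize=self.box)
            tb = cKDTree(_wrap(pb.copy(), self.box), boxsize=self.box)
            hits = ta.query_ball_tree(tb, r)
            ii = np.fromiter(
                (a for a, lst in enumerate(hits) for _ in lst), dtype=np.int64)
            jj = np.fromiter(
                (b for lst in hits for b in lst), dtype=np.int64)
        else:
            delta = pa[:, None, :] - pb[None, :, :]
            delta -= self.box * np.round(delta / self.box)
            d2 = np.sum(delta * delta, axis=2)
            ii, jj = np.nonzero(d2 < r * r)
        gi = self.indices_a[ii]
        gj = self.indices_b[jj]
        if self._excl.size and gi.size:
            code = gi * positions.shape[0] + gj
            keep = ~np.isin(code, self._excl)
            gi, gj = gi[keep], gj[keep]
        self.pairs_i, self.pairs_j = gi, gj
        self._ref = positions[self._tracked].copy()
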