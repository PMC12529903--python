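"""Construction of virtual interaction sites and force back-projection.

The hydrogen-bonding beads (HBO, HBH) and the side-chain reference anchor
(Ref) are virtual: their positions are deterministic functions of backbone
(BB) bead positions and they carry no mass.  Every site is expressed in one
canonical form over three consecutive BB parents (p0, p1, p2):

    site = c0 r0 + c1 r1 + c2 r2 + s * l_HB * n_hat,
    n_hat = (r1 - r0) x (r2 - r1) / ||(r1 - r0) x (r2 - r1)||

with (c0, c1, c2; s) = (2/3, 1/3, 0; +1) for HBO, (1/3, 2/3, 0; -1) for
HBH, and (1/2, 0, 1/2; 0) for Ref (midpoint of the flanking BB beads).
Forces accumulated on a site are transferred to its parents through the
exact Jacobian of this map, including the derivative of the normalized
cross product, so that the total energy gradient is preserved and virtual
beads carry zero net force afterwards.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CollinearBackboneError", "place_virtual_sites",
           "project_virtual_forces"]

#: cross products with squared norm below this are treated as collinear
_COLLINEAR_TOL = 1.0e-8


class CollinearBackboneError(ValueError):
    """Raised when consecutive backbone bonds are collinear, leaving the
    hydrogen-bond site normal undefined."""


def _normals(positions: np.ndarray, parents: np.ndarray,
             labels=None) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    r0 = positions[parents[:, 0]]
    r1 = positions[parents[:, 1]]
    r2 = positions[parents[:, 2]]
    u = r1 - r0
    w = r2 - r1
    c = np.cross(u, w)
    norm = np.linalg.norm(c, axis=1)
    bad = norm < _COLLINEAR_TOL
    if np.any(bad):
        which = np.flatnonzero(bad)
        tag = labels[which[0]] if labels is not None else f"site {which[0]}"
        raise CollinearBackboneError(
            f"collinear consecutive backbone bonds at {tag}: "
            "hydrogen-bond site normal is undefined")
    return u, w, c, norm


def place_virtual_sites(positions: np.ndarray, sites: np.ndarray,
                        parents: np.ndarray, coeffs: np.ndarray,
                        signs: np.ndarray, l_hb: float,
                        labels=None) -> np.ndarray:
    """Fill the virtual-site rows of ``positions`` in place and return it.

    Parameters
    ----------
    sites : (n,) int — bead indices of the virtual sites.
    parents : (n, 3) int — the three BB parent indices per site.
    coeffs : (n, 3) float — barycentric coefficients of the base point.
    signs : (n,) float — ±1 for HBO/HBH normal offset, 0 for Ref.
    l_hb : perpendicular offset from the backbone bond, nm.
    labels : optional per-site labels used in collinearity errors.
    """
    if sites.size == 0:
        return positions
    base = (coeffs[:, 0, None] * positions[parents[:, 0]]
            + coeffs[:, 1, None] * positions[parents[:, 1]]
            + coeffs[:, 2, None] * positions[parents[:, 2]])
    normal_needed = signs != 0
    offset = np.zeros_like(base)
    if np.any(normal_needed):
        sub = parents[normal_needed]
        sub_labels = None if labels is None else [
            labels[i] for i in np.flatnonzero(normal_needed)]
        _, _, c, norm = _normals(positions, sub, sub_labels)
        offset[normal_needed] = (signs[normal_needed, None] * l_hb
                                 * c / norm[:, None])
    positions[sites] = base + offset
    return positions


def project_virtual_forces(forces: np.ndarray, positions: np.ndarray,
                           sites: np.ndarray, parents: np.ndarray,
                           coeffs: np.ndarray, signs: np.ndarray,
                           l_hb: float) -> np.ndarray:
    """Transfer forces from virtual sites onto their BB parents, in place.

    Uses F_p += (d site / d r_p)^T F_site.  The base-point part distributes
    by the barycentric coefficients; the normal part uses, for
    n = c/||c|| with c = u x w,

        g = s * l_HB * (I - n n^T) F / ||c||,
        F_u = w x g,   F_w = g x u,

    added to the parents through u = r1 - r0 and w = r2 - r1.  Virtual-site
    force rows are zeroed afterwards.
    """
    if sites.size == 0:
        return forces
    fv = forces[sites].copy()
    for k in range(3):
        np.add.at(forces, parents[:, k], coeffs[:, k, None] * fv)
    normal_needed = signs != 0
    if np.any(normal_needed):
        sub = parents[normal_needed]
        u, w, c, norm = _normals(positions, sub)
        n_hat = c / norm[:, None]
        f = fv[normal_needed]
        g = (signs[normal_needed, None] * l_hb
             * (f - n_hat * np.sum(n_hat * f, axis=1, keepdims=True))
             / norm[:, None])
        f_u = np.cross(w, g)
        f_w = np.cross(g, u)
        np.add.at(forces, sub[:, 0], -f_u)
        np.add.at(forces, sub[:, 1], f_u - f_w)
        np.add.at(forces, sub[:, 2], f_w)
    forces[sites] = 0.0
    return forces
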