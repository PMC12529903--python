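"""Numba pair-interaction kernels.

These loops are the per-step hot path; everything else in the force field
is vectorised numpy.  Distances use the cubic minimum-image convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def hp_pair_kernel(pos, box, pi, pj, eps_pair, sigma, eps_rep, rc, forces):
    """Shifted 8-6 pair energy/forces over an explicit pair list.

    The potential is shifted so it is zero at the cutoff ``rc`` (the shift
    depends on eps_ij and is applied per pair).  Returns the total energy;
    forces are accumulated in place.
    """
    e = 0.0
    rc2 = rc * rc
    src = sigma / rc
    src8 = src ** 8
    for n in range(pi.size):
        i = pi[n]
        j = pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        eps = eps_pair[n]
        s = sigma / r
        s2 = s * s
        s6 = s2 * s2 * s2
        s8 = s6 * s2
        if r <= sigma:
            phi = eps_rep * s8 - eps * ((4.0 / 3.0) * s6 - 1.0 / 3.0)
            dphi = (-8.0 * eps_rep * s8 + 8.0 * eps * s6) / r
        else:
            phi = (eps_rep - eps) * s8
            dphi = -8.0 * (eps_rep - eps) * s8 / r
        e += phi - (eps_rep - eps) * src8
        fs = -dphi / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return e


@njit(cache=True)
def hb_pair_kernel(pos, box, pi, pj, eps_hb, sigma_hb, forces):
    """Switched 12/6 hydrogen-bond energy/forces over HBO-HBH pairs.

    Identically zero at and beyond r = sigma_hb (smooth quintic switch);
    at r = 0 the energy is exactly -eps_hb and the force vanishes.
    """
    e = 0.0
    for n in range(pi.size):
        i = pi[n]
        j = pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= sigma_hb * sigma_hb:
            continue
        r = np.sqrt(r2)
        q = sigma_hb / (r + sigma_hb)
        q6 = q ** 6
        lj = eps_hb * (q6 * q6 - 2.0 * q6)
        dlj = eps_hb * (-12.0 * q6 * q6 + 12.0 * q6) * q / sigma_hb
        x = r / sigma_hb
        sw = 1.0 - 10.0 * x**3 + 15.0 * x**4 - 6.0 * x**5
        dsw = (-30.0 * x**2 + 60.0 * x**3 - 30.0 * x**4) / sigma_hb
        e += lj * sw
        if r < 1.0e-10:
            continue  # ideal bond: zero force by symmetry
        dphi = dlj * sw + lj * dsw
        fs = -dphi / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return e


@njit(cache=True)
def bond_kernel(pos, box, bi, bj, l0, k, forces):
    """Harmonic bonds V = 1/2 k (r - l0)^2."""
    e = 0.0
    for n in range(bi.size):
        i = bi[n]
        j = bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - l0[n]
        e += 0.5 * k[n] * d * d
        fs = -k[n] * d / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return e
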