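"""Scalar interaction potentials of the 2BPA-Q model.

Two nonbonded forms are used.  Backbone and side-chain beads interact via a
shifted 8-6 Lennard-Jones potential whose attractive well is modulated by
per-bead hydrophobicity strengths λ through a geometric-mean-like
combination rule, ε_ij = ε_hp (λ_i λ_j)^α.  Hydrogen bonding acts between
virtual HBO (acceptor) and HBH (donor) sites through a 12/6 form written in
the shifted variable σ_HB/(r+σ_HB), so that an ideal bond (r = 0) has
energy −ε_HB; a quintic switch takes the potential smoothly to zero at
r = σ_HB, beyond which it vanishes identically.

Functions return energies in kJ/mol for distances in nm; each has a
companion returning (energy, dE/dr) for force evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "combine_epsilon", "phi_hp", "phi_hp_with_derivative",
    "switch_quintic", "phi_hb", "phi_hb_with_derivative",
    "BackbonePotentials", "HarmonicAngle", "CosineTorsion",
    "TabulatedPotential",
]


def combine_epsilon(lambda_i, lambda_j, params: ParameterSet | None = None):
    """Pair interaction strength ε_ij = ε_hp (λ_i λ_j)^α, kJ/mol.

    Symmetric and monotone increasing in each λ.
    """
    p = params or ParameterSet()
    li = np.asarray(lambda_i, dtype=float)
    lj = np.asarray(lambda_j, dtype=float)
    if np.any(li <= 0) or np.any(lj <= 0):
        raise ValueError("interaction strengths lambda must be positive")
    return p.eps_hp * (li * lj) ** p.alpha


def phi_hp(r, eps_ij, params: ParameterSet | None = None):
    """Shifted 8-6 pair potential between BB/SC beads, kJ/mol.

    For r ≤ σ:  ε_rep (σ/r)^8 − ε_ij [ (4/3)(σ/r)^6 − 1/3 ]
    For r ≥ σ:  (ε_rep − ε_ij) (σ/r)^8

    Continuous with continuous first derivative at r = σ.  No cutoff shift
    is applied here; the force field subtracts the value at its cutoff.
    """
    e, _ = phi_hp_with_derivative(r, eps_ij, params)
    return e


def phi_hp_with_derivative(r, eps_ij, params: ParameterSet | None = None):
    p = params or ParameterSet()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance r must be positive")
    eps_ij = np.asarray(eps_ij, dtype=float)
    s = p.sigma / r
    s6 = s ** 6
    s8 = s6 * s * s
    inner = p.eps_rep * s8 - eps_ij * ((4.0 / 3.0) * s6 - 1.0 / 3.0)
    d_inner = (-8.0 * p.eps_rep * s8 + 8.0 * eps_ij * s6) / r
    outer = (p.eps_rep - eps_ij) * s8
    d_outer = -8.0 * (p.eps_rep - eps_ij) * s8 / r
    le = r <= p.sigma
    e = np.where(le, inner, outer)
    de = np.where(le, d_inner, d_outer)
    if e.ndim == 0:
        return float(e), float(de)
    return e, de


def switch_quintic(r, sigma_hb: float):
    """Quintic potential-switch S_V(x) = 1 − 10x³ + 15x⁴ − 6x⁵, x = r/σ_HB.

    S(0) = 1, S(σ_HB) = 0, with zero first and second derivative at both
    ends; monotone decreasing on [0, σ_HB].
    """
    x = np.asarray(r, dtype=float) / sigma_hb
    s = 1.0 - 10.0 * x**3 + 15.0 * x**4 - 6.0 * x**5
    return s if s.ndim else float(s)


def _switch_with_derivative(r, sigma_hb: float):
    x = r / sigma_hb
    s = 1.0 - 10.0 * x**3 + 15.0 * x**4 - 6.0 * x**5
    ds = (-30.0 * x**2 + 60.0 * x**3 - 30.0 * x**4) / sigma_hb
    return s, ds


def phi_hb(r, params: ParameterSet | None = None):
    """Switched hydrogen-bond potential between HBO and HBH sites, kJ/mol.

    ε_HB [ q¹² − 2 q⁶ ] S_V(r)  with q = σ_HB/(r+σ_HB)  for r < σ_HB,
    and exactly zero for r ≥ σ_HB.  phi_hb(0) = −ε_HB (ideal bond).
    """
    e, _ = phi_hb_with_derivative(r, params)
    return e


def phi_hb_with_derivative(r, params: ParameterSet | None = None):
    p = params or ParameterSet()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    q = p.sigma_hb / (r + p.sigma_hb)
    q6 = q ** 6
    lj = p.eps_hb * (q6 * q6 - 2.0 * q6)
    dlj = p.eps_hb * (-12.0 * q6 * q6 + 12.0 * q6) * q / p.sigma_hb
    s, ds = _switch_with_derivative(r, p.sigma_hb)
    e = np.where(r < p.sigma_hb, lj * s, 0.0)
    de = np.where(r < p.sigma_hb, dlj * s + lj * ds, 0.0)
    if e.ndim == 0:
        return float(e), float(de)
    return e, de


# ---------------------------------------------------------------------------
# Pluggable backbone bending / torsion / 1-4 coupling potentials
# ---------------------------------------------------------------------------

@dataclass
class HarmonicAngle:
    """V(θ) = ½ k (θ − θ0)², θ in radians."""

    theta0: float  # radians
    k: float       # kJ/mol/rad^2

    def __call__(self, theta):
        d = theta - self.theta0
        return 0.5 * self.k * d * d, self.k * d


@dataclass
class CosineTorsion:
    """V(φ) = k (1 + cos φ): minimum at the planar trans conformation."""

    k: float  # kJ/mol

    def __call__(self, phi):
        return self.k * (1.0 + np.cos(phi)), -self.k * np.sin(phi)


class TabulatedPotential:
    """Cubic-spline potential from a two-column (coordinate, energy) table.

    The coordinate is in radians for angle/torsion tables.  Torsion tables
    may be marked periodic over [−π, π].
    """

    def __init__(self, x: np.ndarray, v: np.ndarray, periodic: bool = False):
        from scipy.interpolate import CubicSpline

        x = np.asarray(x, dtype=float)
        v = np.asarray(v, dtype=float)
        if x.ndim != 1 or x.shape != v.shape or x.size < 4:
            raise ValueError("table needs matching 1-D columns, >= 4 rows")
        bc = "periodic" if periodic else "not-a-knot"
        if periodic and not np.isclose(v[0], v[-1]):
            v = v.copy()
            v[-1] = v[0]
        self._spline = CubicSpline(x, v, bc_type=bc)
        self._dspline = self._spline.derivative()
        self.x_min, self.x_max = float(x[0]), float(x[-1])
        self.periodic = periodic

    @classmethod
    def from_file(cls, path: str | Path, periodic: bool = False):
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path}: expected two whitespace columns")
        return cls(data[:, 0], data[:, 1], periodic=periodic)

    def __call__(self, x):
        if self.periodic:
            span = self.x_max - self.x_min
            x = (np.asarray(x) - self.x_min) % span + self.x_min
        return self._spline(x), self._dspline(x)


@dataclass
class BackbonePotentials:
    """Bundle of backbone bend / torsion / 1-4 coupling potentials.

    The residue-specific Boltzmann-inverted potentials of the parent
    one-bead model are not redistributable here; the default is a
    non-calibrated stand-in (harmonic bend at the β-region pseudo-angle,
    a weak trans-minimum torsion, no 1-4 coupling) adequate for fixture
    relaxation and aggregate-scale observables.  Calibrated tables can be
    dropped in via :class:`TabulatedPotential`.
    """

    bend: Callable = None
    torsion: Callable = None
    coupling14: Callable | None = None  # V(theta_i, alpha_i) hook; off by default

    @classmethod
    def default(cls, params: ParameterSet) -> "BackbonePotentials":
        return cls(
            bend=HarmonicAngle(np.deg2rad(params.theta_bend), params.k_bend),
            torsion=CosineTorsion(params.k_torsion),
            coupling14=None,
        )
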