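"""Force-field and analysis parameters for the 2BPA-Q polyglutamine model.

All defaults are the published values of the calibrated model: bead sizes
and interaction strengths of the hydrophobic 8-6 pair potential, the
virtual-site hydrogen-bonding scheme, the side-chain restraint, the
Langevin protocol constants, and the aggregation-analysis cutoffs.
Backbone bending/torsion stiffnesses marked *stand-in* below are not part
of the published parameter set (the residue-specific Boltzmann-inverted
backbone potentials are external to it) and are replaceable via
:class:`polyqcg.potentials.BackbonePotentials`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ParameterSet:
    """Every constant of the model, in nm / kJ/mol / ps / K units."""

    # -- bonded backbone --------------------------------------------------
    l_bb: float = 0.38        # BB-BB equilibrium bond length, nm
    k_bond: float = 8038.0    # harmonic bond constant, kJ/mol/nm^2
    # stand-in backbone bending/torsion (non-calibrated; see module docs)
    theta_bend: float = 127.0  # pseudo-bond bending equilibrium, degrees
    k_bend: float = 150.0      # bending constant, kJ/mol/rad^2
    k_torsion: float = 2.0     # 1-cos torsion barrier, kJ/mol (trans minimum)

    # -- nonbonded 8-6 pair potential -------------------------------------
    sigma: float = 0.476      # bead diameter, nm
    eps_hp: float = 13.0      # hydrophobic interaction scale, kJ/mol
    eps_rep: float = 10.0     # repulsive prefactor, kJ/mol
    alpha: float = 0.27       # combination-rule exponent
    lambda_bb: float = 0.64   # backbone-bead relative interaction strength
    lambda_sc: float = 0.58   # side-chain relative interaction strength
    cutoff: float = 2.4 * 0.476  # hp cutoff, nm (energy-shifted to zero)

    # -- hydrogen bonding --------------------------------------------------
    l_hb: float = 0.238       # HB-site perpendicular offset from bond, nm
    sigma_hb: float = 0.42    # HB interaction range, nm
    eps_hb: float = 6.6       # ideal hydrogen-bond energy, kJ/mol

    # -- side chain --------------------------------------------------------
    l_sc: float = 0.424       # SC-BB bond length, nm
    k_sc_bond: float = 8038.0  # SC-BB bond constant, kJ/mol/nm^2
    theta_sc: float = 180.0   # SC-BB-Ref restraint angle, degrees
    k_sc: float = 1000.0      # SC-BB-Ref restraint constant, kJ/mol/rad^2

    # -- masses (equilibrium properties are mass-independent) -------------
    m_bb: float = 56.0        # Da, glutamine backbone fragment
    m_sc: float = 72.0        # Da, glutamine side-chain fragment

    # -- simulation protocol ----------------------------------------------
    temperature: float = 300.0  # K
    dt: float = 0.02            # ps
    tau_friction: float = 2.0   # inverse friction coefficient gamma^-1, ps
    skin: float = 0.2           # neighbor-list skin, nm

    # -- analysis cutoffs --------------------------------------------------
    r_cluster: float = 0.6    # cluster contact cutoff (BB/SC beads), nm
    r_hbond: float = 0.12     # HBO-HBH hydrogen-bond cutoff, nm
    zipper_min: tuple = (0.38, 0.5)  # closest-bead window, nm
    zipper_max: tuple = (1.2, 2.5)   # farthest-bead window, nm

    def __post_init__(self) -> None:
        for name in ("l_bb", "k_bond", "sigma", "eps_hp", "eps_rep",
                     "l_hb", "sigma_hb", "eps_hb", "l_sc", "k_sc",
                     "temperature", "dt", "tau_friction", "cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be positive")
        if not 0.0 < self.lambda_bb <= 1.0:
            raise ValueError("lambda_bb must lie in (0, 1]")
        if not 0.0 < self.lambda_sc <= 1.0:
            raise ValueError("lambda_sc must lie in (0, 1]")
        self.zipper_min = tuple(self.zipper_min)
        self.zipper_max = tuple(self.zipper_max)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zipper_min"] = list(d["zipper_min"])
        d["zipper_max"] = list(d["zipper_max"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "ParameterSet":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)
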