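"""Physical constants in the package's internal unit system.

Lengths are nm, energies kJ/mol, time ps, mass g/mol (Da), temperature K.
This system is internally consistent: 1 kJ/mol = 1 Da nm^2 / ps^2.
"""

#: Boltzmann constant, kJ/mol/K
KB = 0.008314462618

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: Conversion: 1 mol/L expressed as molecules per nm^3
MOLAR_TO_PER_NM3 = N_AVOGADRO / 1.0e24
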