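"""Unit conversions.

Everything inside the package is in Hartree atomic units (lengths in bohr,
polarizabilities and C6 coefficients in a.u.).  Only the xyz reader/writer
converts lengths from/to angstroms.
"""

#: CODATA bohr per angstrom.
BOHR_PER_ANGSTROM = 1.8897259886

ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
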