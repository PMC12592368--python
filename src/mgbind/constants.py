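"""Physical constants and default parameter tables.

All energies are in kJ/mol and all lengths in nm unless a function
explicitly says otherwise (PDB I/O is in Angstrom at the boundary).
"""

#: RT at 310 K (body temperature), kJ/mol.
RT_310 = 2.577

#: Standard-state volume corresponding to a 1 M concentration, nm^3.
V0_STANDARD = 1.661

#: Debye-Hueckel limiting-law coefficient A in water at 310 K, M^-1/2.
DEBYE_HUCKEL_A_310 = 0.519

#: Default van der Waals radii for the pore profiler, nm (per element).
VDW_RADII_NM = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "H": 0.110,
    "P": 0.180,
}

#: Fallback radius for elements missing from the table, nm.
VDW_RADIUS_DEFAULT_NM = 0.170
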