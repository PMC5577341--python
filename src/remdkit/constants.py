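"""Physical constants and per-element parameter tables.

Units follow the package conventions: lengths in nm internally (Å at PDB
boundaries and inside the DSSP-style hydrogen-bond energy), energies in
kcal/mol, temperatures in K, charges in elementary charge units.
"""

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_KE = 332.0636

#: DSSP electrostatic hydrogen-bond prefactor, kcal·Å/mol
DSSP_Q = 27.888

#: Hydrogen bond called when the Kabsch–Sander energy is below this, kcal/mol
HBOND_ENERGY_CUTOFF = -0.5

#: nm per Å
NM_PER_ANGSTROM = 0.1

#: Atomic masses, g/mol (only elements occurring in peptide heavy atoms + H)
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: van der Waals radii for SASA, nm (Bondi-style)
VDW_RADIUS = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
}

#: Default Lennard-Jones parameters per element: (sigma nm, epsilon kcal/mol)
LJ_PARAMS = {
    "H": (0.107, 0.0157),
    "C": (0.340, 0.1094),
    "N": (0.325, 0.1700),
    "O": (0.296, 0.2100),
    "S": (0.356, 0.2500),
}

#: Default intrinsic (Born) radii for the GB model, nm
BORN_RADIUS = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.150,
    "S": 0.180,
}

#: Elements whose heavy atoms count as hydrophobic for SASA partitioning
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})
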