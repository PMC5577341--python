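"""Residue templates: heavy-atom composition and simple charge assignments.

Templates carry heavy atoms plus the backbone amide H (needed for the
hydrogen-bond-based secondary-structure assignment); side-chain hydrogens are
deliberately absent — every analysis in the package is defined on heavy atoms.

The bundled charge set is a deliberately simple, synthetic assignment (neutral
backbone; integer formal charges concentrated on the titratable side-chain
groups). It is not a published force field; it exists so that the energetics
module has well-defined inputs for peptide topologies.
"""

from __future__ import annotations

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: Backbone heavy atoms shared by every residue, in output order.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Side-chain heavy atoms per residue, in output order (standard PDB names).
SIDECHAIN_ATOMS = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

#: Neutral backbone partial charges (sum exactly 0); amide H included.
BACKBONE_CHARGES = {"N": -0.35, "H": 0.25, "CA": 0.10, "C": 0.50, "O": -0.50}

#: Side-chain partial charges for charged groups; atoms not listed carry 0.
#: ASP/GLU carry a formal −1, LYS/ARG a formal +1; HIS is neutral by default
#: (protonation is configurable at topology-build time).
SIDECHAIN_CHARGES = {
    "ASP": {"CG": 0.60, "OD1": -0.80, "OD2": -0.80},
    "GLU": {"CD": 0.60, "OE1": -0.80, "OE2": -0.80},
    "LYS": {"CE": 0.20, "NZ": 0.80},
    "ARG": {"CZ": 0.50, "NH1": 0.25, "NH2": 0.25},
}

#: Extra charge on a protonated histidine (applied when requested).
HIS_PROTONATED_CHARGES = {"ND1": 0.50, "NE2": 0.50}


def element_of(atom_name: str) -> str:
    """Infer the element from a standard peptide heavy-atom/amide-H name."""
    return atom_name[0]


def heavy_atom_names(resname: str, oxt: bool = False) -> tuple[str, ...]:
    """Heavy atoms of one residue in canonical order (backbone, side chain[, OXT])."""
    try:
        side = SIDECHAIN_ATOMS[resname]
    except KeyError:
        raise KeyError(f"unknown residue name {resname!r}") from None
    atoms = BACKBONE_ATOMS + side
    if oxt:
        atoms = atoms + ("OXT",)
    return atoms
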