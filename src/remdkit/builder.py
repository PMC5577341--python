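"""Ideal-geometry peptide construction.

A small internal-coordinate (NeRF) engine builds backbones from per-residue
(φ, ψ) dihedrals with standard bond lengths/angles, places C=O, the amide H
(anti to the preceding carbonyl — the convention hydrogen-bond-based
secondary-structure assignment assumes), Cβ, and schematic side-chain heavy
atoms extended along the Cα→Cβ direction. Side-chain geometry is deliberately
schematic: the analyses that consume these structures (contacts, SASA,
energetics on synthetic ensembles) need plausible excluded volume, not
rotamer realism.

Also provides a crude Cα-trace → backbone reconstruction used to run
secondary-structure assignment on bead-chain Monte Carlo frames.

Internal lengths here are in Å; public functions return nm.
"""

from __future__ import annotations

import numpy as np

from . import templates
from .core import Topology

# standard backbone internal coordinates, Å / degrees
B_N_CA, B_CA_C, B_C_N, B_C_O, B_N_H, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.01, 1.53
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O, A_N_CA_CB = 121.7, 111.2, 116.2, 120.8, 110.4
D_N_C_CA_CB = -122.6  # improper placing CB

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-140.0, 135.0),
    "ppii": (-75.0, 145.0),
}


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom D given A-B-C with |CD|=bond, ∠BCD=angle, dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # collinear support: pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, bc)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, ref)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi, psi, omega=None):
    """Build N/CA/C/O/H backbone coordinates (Å) for given dihedrals.

    ``phi[0]`` and ``psi[-1]`` are not geometrically meaningful but must be
    supplied for uniformity. Returns dict of (n, 3) arrays; H[0] is NaN (no
    preceding carbonyl).
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    omega = np.full(n_res, 180.0) if omega is None else np.asarray(omega, float)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed first residue
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    C[0] = place_atom(
        np.array([0.0, -1.0, 0.0]), N[0], CA[0], B_CA_C, A_N_CA_C, phi[0]
    )
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, omega[i - 1])
        C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi[i])
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        if i + 1 < n_res:
            # carbonyl O anti to the next amide N in the peptide plane
            O[i] = place_atom(N[i + 1], CA[i], C[i], B_C_O, A_CA_C_O, 180.0)
        else:
            O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi[i] + 180.0)
    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        H[i] = amide_h(N[i], C[i - 1], O[i - 1])
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def amide_h(n_pos, c_prev, o_prev):
    """Amide H: 1.01 Å from N, anti to the preceding C=O (DSSP convention)."""
    d = c_prev - o_prev
    return n_pos + B_N_H * d / np.linalg.norm(d)


def _sidechain_positions(resname, n, ca, c, oxt_pos=None):
    """Schematic heavy side chain: CB ideal, the rest marched outward."""
    names = templates.SIDECHAIN_ATOMS[resname]
    out = {}
    if not names:
        return out
    cb = place_atom(n, c, ca, B_CA_CB, A_N_CA_CB, D_N_C_CA_CB)
    out["CB"] = cb
    direction = cb - ca
    direction /= np.linalg.norm(direction)
    # a fixed perpendicular for a gentle zig-zag (avoids collinear stacks)
    perp = np.cross(direction, c - ca)
    perp /= np.linalg.norm(perp)
    prev = cb
    for k, name in enumerate(names[1:], start=1):
        offset = 1.5 * direction + (0.5 if k % 2 else -0.5) * perp
        # branch atoms (e.g. OD2, CG2) fork sideways off the same parent
        if name.endswith("2") and name[:-1] + "1" in out:
            parent = out[name[:-1] + "1"]
            pos = parent + 1.3 * perp * (1 if k % 2 else -1) + 0.4 * direction
        else:
            pos = prev + offset
            prev = pos
        out[name] = pos
    return out


def build_peptide_coords(topology: Topology, phi, psi, omega=None) -> np.ndarray:
    """Full heavy-atom (+amide H) coordinates (nm) for a single-chain topology."""
    bb = build_backbone(phi, psi, omega)
    return assemble_coords(topology, bb)


def assemble_coords(topology: Topology, bb: dict) -> np.ndarray:
    """Map per-residue backbone dict (Å) onto topology atom order, in nm."""
    n_res = topology.n_residues
    for key in ("N", "CA", "C", "O"):
        if bb[key].shape[0] != n_res:
            raise ValueError("backbone length does not match topology")
    coords = np.zeros((topology.n_atoms, 3))
    side_cache = {}
    for i, (name, rid) in enumerate(zip(topology.atom_names, topology.atom_resid)):
        if name in ("N", "CA", "C", "O"):
            coords[i] = bb[name][rid]
        elif name == "H":
            h = bb["H"][rid]
            if np.any(np.isnan(h)):  # chain start: synthesize from local frame
                h = amide_h(bb["N"][rid], bb["CA"][rid],
                            bb["CA"][rid] + (bb["CA"][rid] - bb["C"][rid]))
            coords[i] = h
        elif name == "OXT":
            coords[i] = bb["O"][rid] + (bb["O"][rid] - bb["CA"][rid]) * 0.4
        else:
            if rid not in side_cache:
                side_cache[rid] = _sidechain_positions(
                    topology.residue_names[rid], bb["N"][rid], bb["CA"][rid],
                    bb["C"][rid],
                )
            coords[i] = side_cache[rid][name]
    return coords * 0.1  # Å → nm


def backbone_from_ca(ca_nm: np.ndarray) -> dict:
    """Reconstruct an approximate backbone (nm) from a Cα trace (nm).

    N and C are placed on the virtual bonds to the neighbouring Cα atoms, the
    carbonyl O perpendicular to the local chain plane, H anti to the
    preceding C=O. Ends are extrapolated. Crude by design — the same
    coordinates are fed to both this package's assigner and any reference
    assignment, so comparisons are like-for-like.
    """
    ca = np.asarray(ca_nm, float) * 10.0  # work in Å
    n_res = len(ca)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    virt = np.empty((n_res, 3))
    virt[:-1] = ca[1:] - ca[:-1]
    virt[-1] = virt[-2]
    prev = np.empty((n_res, 3))
    prev[1:] = virt[:-1]
    prev[0] = virt[0]

    def unit(v):
        return v / np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), 1e-9)

    u_next, u_prev = unit(virt), unit(prev)
    N = ca - 1.46 * unit(u_prev + 0.35 * u_next)
    C = ca + 1.52 * unit(u_next + 0.35 * u_prev)
    normal = np.cross(u_prev, u_next)
    nn = np.linalg.norm(normal, axis=1, keepdims=True)
    fallback = np.cross(u_next, np.array([0.0, 0.0, 1.0]))
    normal = np.where(nn > 1e-6, normal / np.maximum(nn, 1e-9), unit(fallback))
    O = C + 1.23 * normal
    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        H[i] = amide_h(N[i], C[i - 1], O[i - 1])
    return {"N": N, "CA": ca, "C": C, "O": O, "H": H}
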