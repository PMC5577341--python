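"""Single-trajectory MM-GB/SA binding-energy decomposition.

Interchain molecular-mechanics terms (Coulomb, Lennard-Jones), a
generalized-Born polar solvation term (HCT pairwise-descreening effective
radii in the Still et al. interpolation), and a SASA-proportional nonpolar
term. In the single-trajectory approximation the intra-chain MM terms cancel
between complex and separated species, so only cross-chain pairs enter
ΔE_VdW and ΔE_elec; the solvation terms are recomputed per species
(complex, chain A alone, chain B alone) with effective radii re-derived for
each species. No configurational-entropy term is included.

ΔG_bind = ΔE_VdW + ΔE_elec + ΔG_polar + ΔG_nonpolar, each mean ± block SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COULOMB_KE
from .core import Ensemble, Topology
from .geometry import sasa
from .landscape import block_standard_error

_NM2A = 10.0
_MIN_R_NM = 0.01  # clash guard for MM pair terms


@dataclass(frozen=True)
class SolventModel:
    """Implicit-solvent parameters for the GB/SA terms.

    gamma (kcal/mol/Å²) and offset b (kcal/mol) define the nonpolar term
    G_np = γ·SASA + b·n_molecules; the HCT scale multiplies the descreening
    radii of neighbouring atoms.
    """

    solvent_dielectric: float = 80.0
    solute_dielectric: float = 1.0
    surface_tension: float = 0.00542
    nonpolar_offset: float = 0.92
    probe_radius: float = 0.14
    hct_scale: float = 0.8
    sasa_points: int = 240

    def __post_init__(self):
        if self.solvent_dielectric < 1 or self.solute_dielectric < 1:
            raise ValueError("dielectrics must be ≥ 1")
        if self.surface_tension < 0:
            raise ValueError("surface tension must be non-negative")


def _cross_distances(frame, group_a, group_b):
    a = np.asarray(frame)[np.asarray(group_a, int)]
    b = np.asarray(frame)[np.asarray(group_b, int)]
    r = np.sqrt(np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1))
    if r.min() < _MIN_R_NM:
        raise ValueError(f"atom clash: pair distance {r.min():.4f} nm < 0.01 nm")
    return r


def coulomb_energy(topology: Topology, frame, group_a, group_b) -> float:
    """Cross-group Coulomb energy, kcal/mol (no cutoff, no periodicity)."""
    ga, gb = np.asarray(group_a, int), np.asarray(group_b, int)
    if np.intersect1d(ga, gb).size:
        raise ValueError("groups overlap")
    r = _cross_distances(frame, ga, gb) * _NM2A
    qq = topology.charges[ga][:, None] * topology.charges[gb][None, :]
    return float(COULOMB_KE * np.sum(qq / r))


def lj_energy(topology: Topology, frame, group_a, group_b) -> float:
    """Cross-group Lennard-Jones energy with Lorentz–Berthelot combination."""
    ga, gb = np.asarray(group_a, int), np.asarray(group_b, int)
    if np.intersect1d(ga, gb).size:
        raise ValueError("groups overlap")
    r = _cross_distances(frame, ga, gb)
    sig = 0.5 * (topology.sigmas[ga][:, None] + topology.sigmas[gb][None, :])
    eps = np.sqrt(topology.epsilons[ga][:, None] * topology.epsilons[gb][None, :])
    sr6 = (sig / r) ** 6
    return float(np.sum(4.0 * eps * (sr6**2 - sr6)))


def hct_effective_radii(
    topology: Topology, frame, group, scale: float = 0.8
) -> np.ndarray:
    """Effective Born radii (nm) by Hawkins–Cramer–Truhlar descreening.

    An isolated atom recovers its intrinsic radius exactly; neighbours
    displace solvent, so burial grows the effective radius (1/R_i shrinks).
    """
    g = np.asarray(group, int)
    rho = topology.born_radii[g]
    if np.any(rho <= 0):
        raise ValueError("Born radii must be positive")
    x = np.asarray(frame)[g]
    n = len(g)
    r = np.sqrt(np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1))
    inv = 1.0 / rho
    for i in range(n):
        s_rho = scale * rho
        rij = r[i]
        mask = np.ones(n, bool)
        mask[i] = False
        # atoms fully enclosed in atom i's sphere do not descreen it
        mask &= rij + s_rho > rho[i]
        j = np.flatnonzero(mask)
        if j.size == 0:
            continue
        rj, sj = rij[j], s_rho[j]
        L = np.maximum(np.abs(rj - sj), rho[i])
        U = rj + sj
        integral = 0.5 * (
            1.0 / L
            - 1.0 / U
            + (rj / 4.0) * (1.0 / U**2 - 1.0 / L**2)
            + (1.0 / (2.0 * rj)) * np.log(L / U)
            + (sj**2 / (4.0 * rj)) * (1.0 / L**2 - 1.0 / U**2)
        )
        inv[i] -= integral.sum()
    return 1.0 / np.maximum(inv, 1e-6)


def gb_polar_solvation(
    topology: Topology, frame, group, model: SolventModel = SolventModel()
) -> float:
    """Generalized-Born polar solvation free energy of one group, kcal/mol.

    Still-style pair function f_GB = sqrt(r² + R_i R_j exp(−r²/4R_iR_j));
    the self term (i = j) reduces to the Born formula with the effective
    radius.
    """
    g = np.asarray(group, int)
    q = topology.charges[g]
    R = hct_effective_radii(topology, frame, g, model.hct_scale) * _NM2A
    x = np.asarray(frame)[g] * _NM2A
    r2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    RR = R[:, None] * R[None, :]
    fgb = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    pref = -0.5 * COULOMB_KE * (
        1.0 / model.solute_dielectric - 1.0 / model.solvent_dielectric
    )
    return float(pref * np.sum(q[:, None] * q[None, :] / fgb))


@dataclass
class EnergyDecomposition:
    """Binding-energy components, kcal/mol, each mean ± block SE."""

    dE_vdw: tuple
    dE_elec: tuple
    dG_polar: tuple
    dG_nonpolar: tuple
    dG_bind: tuple
    per_frame: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        total = (
            self.dE_vdw[0] + self.dE_elec[0] + self.dG_polar[0]
            + self.dG_nonpolar[0]
        )
        if abs(total - self.dG_bind[0]) > 1e-9:
            raise ValueError("components do not sum to the binding energy")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("dE_vdw", *self.dE_vdw),
            ("dE_elec", *self.dE_elec),
            ("dG_polar", *self.dG_polar),
            ("dG_nonpolar", *self.dG_nonpolar),
            ("dG_bind", *self.dG_bind),
        ]
        return pd.DataFrame(rows, columns=["component", "mean_kcal_mol", "se_kcal_mol"])


def mmgbsa_binding(
    ensemble: Ensemble,
    chain_a: str,
    chain_b: str,
    model: SolventModel = SolventModel(),
    n_blocks: int = 4,
) -> EnergyDecomposition:
    """Single-trajectory MM-GB/SA decomposition of interchain binding."""
    if ensemble.n_frames == 0:
        raise ValueError("ensemble is empty")
    top = ensemble.topology
    for c in (chain_a, chain_b):
        if c not in top.chain_ids:
            raise ValueError(f"chain {c!r} not in topology")
    ga = top.atom_indices(chain_id=chain_a)
    gb = top.atom_indices(chain_id=chain_b)
    gc = np.concatenate([ga, gb])
    order = np.argsort(ensemble.times, kind="stable")
    rows = []
    for fi in order:
        frame = ensemble.coords[fi]
        vdw = lj_energy(top, frame, ga, gb)
        elec = coulomb_energy(top, frame, ga, gb)
        polar = (
            gb_polar_solvation(top, frame, gc, model)
            - gb_polar_solvation(top, frame, ga, model)
            - gb_polar_solvation(top, frame, gb, model)
        )
        s_c, _ = sasa(frame, top, model.probe_radius, model.sasa_points,
                      atom_indices=gc)
        s_a, _ = sasa(frame, top, model.probe_radius, model.sasa_points,
                      atom_indices=ga)
        s_b, _ = sasa(frame, top, model.probe_radius, model.sasa_points,
                      atom_indices=gb)
        # the offset b counts molecules per species: 2 − 1 − 1 = 0 net
        nonpolar = model.surface_tension * (s_c - s_a - s_b) + \
            model.nonpolar_offset * (2 - 1 - 1)
        rows.append((vdw, elec, polar, nonpolar))
    df = pd.DataFrame(rows, columns=["vdw", "elec", "polar", "nonpolar"])
    df["bind"] = df.sum(axis=1)

    def stat(col):
        return (float(df[col].mean()), block_standard_error(df[col], n_blocks))

    comps = [stat(c) for c in ("vdw", "elec", "polar", "nonpolar")]
    # the total's mean is the exact sum of the component means so the
    # decomposition identity holds to machine precision even for extreme
    # per-frame magnitudes
    bind = (sum(m for m, _ in comps), block_standard_error(df["bind"], n_blocks))
    return EnergyDecomposition(*comps, bind, per_frame=df)
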