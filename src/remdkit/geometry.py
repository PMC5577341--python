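"""Scalar and pairwise geometric observables.

Radius of gyration, Kabsch superposition and RMSD, contact maps with block
errors, salt-bridge frequencies, Shrake–Rupley SASA, and the two reaction
coordinates (normalized strand count in CHC∪CTR and normalized CHC–CTR Cα
contact count) used to span the free-energy landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Ensemble, RegionScheme, Topology
from .landscape import RCSeries, block_standard_error

#: default Cα–Cα contact cutoff (field-standard), nm
CA_CONTACT_CUTOFF = 0.65
#: default heavy-atom contact / salt-bridge N–O cutoff, nm
HEAVY_CONTACT_CUTOFF = 0.40
#: theoretical maximum number of CHC×CTR residue pairs (5 × 13)
CHC_CTR_MAX_PAIRS = 65


def radius_of_gyration(frame, topology: Topology, selection) -> float:
    """Mass-weighted radius of gyration (nm) over the selected atoms."""
    sel = np.asarray(selection, int)
    if sel.size == 0:
        raise ValueError("empty selection")
    x = np.asarray(frame)[sel]
    m = topology.masses()[sel]
    com = np.average(x, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((x - com) ** 2, axis=1), weights=m)))


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred p onto centred q (Kabsch)."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(frame_a, frame_b, selection=None, superpose: bool = True) -> float:
    """RMSD (nm) between two frames, optionally after optimal superposition."""
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if selection is not None:
        sel = np.asarray(selection, int)
        a, b = a[sel], b[sel]
    if a.shape != b.shape:
        raise ValueError("selections differ in atom count")
    if superpose:
        if len(a) < 3:
            raise ValueError("superposition needs at least 3 atoms")
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a = a @ kabsch_rotation(a, b).T
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class ScalarSeries:
    """A timed scalar observable with an optional centred moving average."""

    times: np.ndarray
    values: np.ndarray
    units: str = ""
    ma_window: float | None = None
    moving_average: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ps": self.times, "value": self.values})
        if self.moving_average is not None:
            df["moving_average"] = self.moving_average
        return df


def centered_moving_average(times, values, window: float) -> np.ndarray:
    """Centred moving average over a time window (ps), truncated at edges."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    out = np.empty_like(values)
    half = window / 2.0
    for i, t in enumerate(times):
        mask = (times >= t - half) & (times <= t + half)
        out[i] = values[mask].mean()
    return out


def rmsd_series(
    ensemble: Ensemble,
    reference_frame,
    selection,
    ma_window: float | None = None,
) -> ScalarSeries:
    """Per-frame superposed RMSD (nm) to a reference, with moving average."""
    vals = np.array(
        [
            kabsch_rmsd(ensemble.coords[i], reference_frame, selection)
            for i in range(ensemble.n_frames)
        ]
    )
    ma = None
    if ma_window is not None:
        dt = np.diff(np.sort(np.unique(ensemble.times)))
        if dt.size and ma_window < dt.min():
            raise ValueError("moving-average window smaller than sampling interval")
        ma = centered_moving_average(ensemble.times, vals, ma_window)
    return ScalarSeries(ensemble.times, vals, "nm", ma_window, ma)


@dataclass
class ContactMap:
    """Residue-pair contact probabilities with block standard errors."""

    residues_a: np.ndarray  # global residue ordinals (0-based)
    residues_b: np.ndarray
    probability: np.ndarray
    se: np.ndarray
    mode: str
    cutoff: float
    min_seq_sep: int

    def to_frame(self, topology: Topology | None = None) -> pd.DataFrame:
        rows = []
        for i, ra in enumerate(self.residues_a):
            for j, rb in enumerate(self.residues_b):
                rows.append((int(ra) + 1, int(rb) + 1,
                             self.probability[i, j], self.se[i, j]))
        return pd.DataFrame(
            rows, columns=["residue_a", "residue_b", "probability", "se"]
        )


def _residue_min_dist_contacts(coords, atom_groups_a, atom_groups_b, cutoff):
    """(F, A, B) bool: any-atom pair within cutoff, per frame."""
    F = coords.shape[0]
    out = np.zeros((F, len(atom_groups_a), len(atom_groups_b)), bool)
    for i, ga in enumerate(atom_groups_a):
        xa = coords[:, ga]  # (F, na, 3)
        for j, gb in enumerate(atom_groups_b):
            xb = coords[:, gb]
            d2 = np.sum(
                (xa[:, :, None, :] - xb[:, None, :, :]) ** 2, axis=-1
            )
            out[:, i, j] = d2.min(axis=(1, 2)) < cutoff**2
    return out


def contact_map(
    ensemble: Ensemble,
    residues_a,
    residues_b,
    mode: str = "ca",
    cutoff: float = CA_CONTACT_CUTOFF,
    min_seq_sep: int = 3,
    n_blocks: int = 4,
) -> ContactMap:
    """Residue–residue contact probability map.

    ``mode='ca'`` counts Cα–Cα distances below the cutoff; ``mode='heavy'``
    the minimum heavy-atom distance. When the two residue sets coincide
    (intramolecular map) pairs with |i−j| < ``min_seq_sep`` are zeroed.
    Block standard errors follow the contiguous-time-block protocol.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("ca", "heavy"):
        raise ValueError(f"unknown mode {mode!r}")
    top = ensemble.topology
    ra = np.asarray(residues_a, int)
    rb = np.asarray(residues_b, int)
    intra = np.array_equal(ra, rb)
    order = np.argsort(ensemble.times, kind="stable")
    coords = ensemble.coords[order]
    if mode == "ca":
        ca = top.backbone_indices()["CA"]
        ia, ib = ca[ra], ca[rb]
        if np.any(ia < 0) or np.any(ib < 0):
            raise ValueError("missing CA atom in selection")
        da = coords[:, ia][:, :, None, :] - coords[:, ib][:, None, :, :]
        contacts = np.sqrt(np.sum(da**2, axis=-1)) < cutoff
    else:
        groups_a = [top.atom_indices(residue_ordinals=[r], heavy_only=True) for r in ra]
        groups_b = [top.atom_indices(residue_ordinals=[r], heavy_only=True) for r in rb]
        contacts = _residue_min_dist_contacts(coords, groups_a, groups_b, cutoff)
    if intra:
        sep = np.abs(ra[:, None] - rb[None, :])
        contacts &= sep >= min_seq_sep
    prob = contacts.mean(axis=0)
    F = contacts.shape[0]
    m = F // n_blocks
    bm = contacts[: m * n_blocks].reshape(n_blocks, m, *prob.shape).mean(axis=1)
    se = bm.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return ContactMap(ra, rb, prob, se, mode, cutoff, min_seq_sep)


@dataclass
class DifferenceMap:
    """Masked bound-minus-free contact-probability difference."""

    difference: np.ndarray
    threshold: float
    residues_a: np.ndarray
    residues_b: np.ndarray


def contact_difference(
    map_bound: ContactMap, map_free: ContactMap, threshold: float = 0.06
) -> DifferenceMap:
    """Bound minus free; entries with |Δ| ≤ threshold are masked to 0."""
    if map_bound.probability.shape != map_free.probability.shape:
        raise ValueError("contact maps have different shapes")
    delta = map_bound.probability - map_free.probability
    delta = np.where(np.abs(delta) > threshold, delta, 0.0)
    return DifferenceMap(delta, threshold, map_bound.residues_a, map_bound.residues_b)


def per_residue_contact_count(
    ensemble: Ensemble,
    chain_a: str,
    chain_b: str,
    cutoff: float = HEAVY_CONTACT_CUTOFF,
    n_blocks: int = 4,
):
    """Mean interchain heavy-atom contact count per residue of ``chain_b``.

    For each residue of chain_b, counts atom pairs (one atom from the
    residue, one from chain_a) closer than the cutoff, averaged over frames.
    Returns (means, ses) arrays over chain_b residues.
    """
    if chain_a == chain_b:
        raise ValueError("chains must be distinct")
    top = ensemble.topology
    atoms_a = top.atom_indices(chain_id=chain_a, heavy_only=True)
    res_b = top.chain_residue_ordinals(chain_b)
    order = np.argsort(ensemble.times, kind="stable")
    coords = ensemble.coords[order]
    xa = coords[:, atoms_a]
    counts = np.zeros((ensemble.n_frames, len(res_b)))
    for j, r in enumerate(res_b):
        gb = top.atom_indices(residue_ordinals=[r], heavy_only=True)
        xb = coords[:, gb]
        d2 = np.sum((xb[:, :, None, :] - xa[:, None, :, :]) ** 2, axis=-1)
        counts[:, j] = (d2 < cutoff**2).sum(axis=(1, 2))
    means = counts.mean(axis=0)
    ses = np.array([block_standard_error(counts[:, j], n_blocks) for j in range(len(res_b))])
    return means, ses


_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}


def salt_bridge_frequency(
    ensemble: Ensemble,
    acidic_res: int,
    basic_res: int,
    cutoff: float = HEAVY_CONTACT_CUTOFF,
    n_blocks: int = 4,
) -> tuple[float, float]:
    """Fraction of frames (in %) with the salt bridge formed, ± block SE.

    Residues are 0-based global ordinals. A frame counts when the minimum
    distance between the acidic carboxylate oxygens and the basic side-chain
    nitrogens is below the cutoff (default 0.4 nm).
    """
    top = ensemble.topology
    for res, table, kind in (
        (acidic_res, _ACIDIC_ATOMS, "acidic"),
        (basic_res, _BASIC_ATOMS, "basic"),
    ):
        if top.residue_names[res] not in table:
            raise ValueError(
                f"residue {top.residue_names[res]} is not a supported {kind} residue"
            )
    oa = top.atom_indices(
        residue_ordinals=[acidic_res],
        names=_ACIDIC_ATOMS[top.residue_names[acidic_res]],
    )
    nb = top.atom_indices(
        residue_ordinals=[basic_res],
        names=_BASIC_ATOMS[top.residue_names[basic_res]],
    )
    if oa.size == 0 or nb.size == 0:
        raise ValueError("residue lacks the required functional-group atoms")
    order = np.argsort(ensemble.times, kind="stable")
    coords = ensemble.coords[order]
    d2 = np.sum(
        (coords[:, oa][:, :, None, :] - coords[:, nb][:, None, :, :]) ** 2, axis=-1
    )
    bridged = d2.min(axis=(1, 2)) < cutoff**2
    return (
        float(bridged.mean() * 100.0),
        block_standard_error(bridged * 100.0, n_blocks),
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere quadrature points (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def sasa(
    frame,
    topology: Topology,
    probe: float = 0.14,
    n_points: int = 960,
    subset: str = "all",
    atom_indices=None,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Returns (total Å², per-atom Å² array over the selected atoms). The
    ``subset='hydrophobic'`` total sums the contributions of atoms flagged
    hydrophobic (carbon and sulfur heavy atoms). ``atom_indices`` restricts
    the molecule (e.g. a single chain); the probe is in nm.
    """
    if n_points < 60:
        raise ValueError("need at least 60 quadrature points")
    if subset not in ("all", "hydrophobic"):
        raise ValueError(f"unknown subset {subset!r}")
    x = np.asarray(frame, float)
    idx = (
        np.arange(topology.n_atoms)
        if atom_indices is None
        else np.asarray(atom_indices, int)
    )
    x = x[idx]
    radii = topology.vdw_radii()[idx] + probe
    sphere = _fibonacci_sphere(n_points)
    n = len(idx)
    per_atom = np.zeros(n)
    # neighbour prefilter
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    rsum2 = (radii[:, None] + radii[None, :]) ** 2
    # coincident equal-radius atoms: the lowest index keeps the surface
    duplicate = np.zeros(n, bool)
    for i in range(n):
        same = (d2[i] < 1e-16) & (np.abs(radii - radii[i]) < 1e-12)
        same[i:] = False
        duplicate[i] = same.any()
    for i in range(n):
        if duplicate[i]:
            continue
        neigh = np.flatnonzero(
            (d2[i] < rsum2[i]) & (np.arange(n) != i) & ~duplicate
        )
        pts = x[i] + radii[i] * sphere
        if neigh.size:
            dd = np.sum((pts[:, None, :] - x[neigh][None, :, :]) ** 2, axis=-1)
            buried = (dd < radii[neigh][None, :] ** 2).any(axis=1)
        else:
            buried = np.zeros(n_points, bool)
        frac = 1.0 - buried.mean()
        per_atom[i] = 4.0 * np.pi * (radii[i] * 10.0) ** 2 * frac  # nm² → Å²
    if subset == "hydrophobic":
        total = float(per_atom[topology.hydrophobic[idx]].sum())
    else:
        total = float(per_atom.sum())
    return total, per_atom


def reaction_coordinates(
    ss_labels,
    frame,
    topology: Topology,
    scheme: RegionScheme,
    ca_cutoff: float = CA_CONTACT_CUTOFF,
    norm_pairs: int = CHC_CTR_MAX_PAIRS,
    chain_id: str | None = None,
) -> tuple[float, float]:
    """(nbeta, ncontact) for one frame.

    nbeta = strand-labelled residues among CHC∪CTR / 18; ncontact = CHC–CTR
    Cα pairs within the cutoff / ``norm_pairs``, clipped to [0, 1].
    ``ss_labels`` may be five-class strings or integer codes aligned with the
    chain's residues.
    """
    chain = chain_id or topology.chain_ids[0]
    chain_res = topology.chain_residue_ordinals(chain)
    try:
        chc = scheme.residues("CHC")
        ctr = scheme.residues("CTR")
    except KeyError as exc:
        raise ValueError("region scheme must define CHC and CTR") from exc
    labels = np.asarray(ss_labels)
    if labels.dtype.kind in "iu":
        from .secstruct import CLASSES

        strand = labels == CLASSES.index("STRAND")
    else:
        strand = labels == "STRAND"
    # 1-based region indices → global residue ordinals of the chain
    both = chain_res[[r - 1 for r in chc + ctr]]
    nbeta = float(strand[both].sum()) / len(both)
    ca = topology.backbone_indices()["CA"][chain_res]
    x = np.asarray(frame, float)
    xc = x[ca[[r - 1 for r in chc]]]
    xt = x[ca[[r - 1 for r in ctr]]]
    d = np.sqrt(np.sum((xc[:, None, :] - xt[None, :, :]) ** 2, axis=-1))
    ncontact = min(1.0, float((d < ca_cutoff).sum()) / norm_pairs)
    return nbeta, ncontact


def rc_series(
    ensemble: Ensemble,
    labels: np.ndarray,
    scheme: RegionScheme | None = None,
    ca_cutoff: float = CA_CONTACT_CUTOFF,
    norm_pairs: int = CHC_CTR_MAX_PAIRS,
    chain_id: str | None = None,
) -> RCSeries:
    """Vectorised per-frame reaction coordinates for a whole ensemble."""
    from .secstruct import CLASSES

    scheme = scheme or RegionScheme()
    top = ensemble.topology
    chain = chain_id or top.chain_ids[0]
    chain_res = top.chain_residue_ordinals(chain)
    chc = [r - 1 for r in scheme.residues("CHC")]
    ctr = [r - 1 for r in scheme.residues("CTR")]
    both = chain_res[chc + ctr]
    labels = np.asarray(labels)
    strand = labels[:, both] == CLASSES.index("STRAND")
    nbeta = strand.sum(axis=1) / len(both)
    ca = top.backbone_indices()["CA"][chain_res]
    xc = ensemble.coords[:, ca[chc]]
    xt = ensemble.coords[:, ca[ctr]]
    d2 = np.sum((xc[:, :, None, :] - xt[:, None, :, :]) ** 2, axis=-1)
    ncontact = np.minimum(
        1.0, (d2 < ca_cutoff**2).sum(axis=(1, 2)) / norm_pairs
    )
    return RCSeries(nbeta, ncontact, ensemble.times)
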