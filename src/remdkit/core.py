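"""Domain types for peptide ensembles.

`Topology` describes chains/residues/atoms with per-atom force-field
parameters; `Ensemble` holds ordered coordinate frames (nm) with per-frame
time/replica/temperature metadata; `RegionScheme` names residue ranges on the
42-mer (NTR 1–16, CHC 17–21, turn 22–29, CTR 30–42, derived preCHC 11–16).

Residue numbering is 1-based inclusive throughout, coordinates are stored in
nm, times in ps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants, templates

#: Aβ42 one-letter sequence and the N-terminal hexapeptide variants (position
#: 2 is A/V/T in WT/A2V/A2T).
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
HEXAPEPTIDES = {"WT": "DAEFRH", "A2V": "DVEFRH", "A2T": "DTEFRH"}


@dataclass(frozen=True)
class SequenceLibrary:
    """The study sequences: the 42-mer and the three hexapeptide variants."""

    abeta42: str = ABETA42_SEQUENCE
    hexapeptides: dict = field(default_factory=lambda: dict(HEXAPEPTIDES))

    def __post_init__(self):
        if len(self.abeta42) != 42:
            raise ValueError("Aβ42 sequence must have 42 residues")
        for name, seq in self.hexapeptides.items():
            if len(seq) != 6:
                raise ValueError(f"hexapeptide {name} must have 6 residues")
            if seq[0] != "D" or seq[2:] != "EFRH" or seq[1] not in "AVT":
                raise ValueError(
                    f"hexapeptide {name} must match D[AVT]EFRH, got {seq!r}"
                )


@dataclass(frozen=True)
class RegionScheme:
    """Named 1-based inclusive residue ranges on the 42-mer."""

    regions: dict = field(
        default_factory=lambda: {
            "NTR": (1, 16),
            "CHC": (17, 21),
            "turn": (22, 29),
            "CTR": (30, 42),
            "preCHC": (11, 16),
        }
    )
    #: The four primary (partitioning) regions; derived regions may overlap.
    primary: tuple = ("NTR", "CHC", "turn", "CTR")

    def __post_init__(self):
        covered = []
        for name in self.primary:
            lo, hi = self.regions[name]
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, max(covered) + 1)):
            raise ValueError("primary regions must partition 1..N")

    def residues(self, name: str) -> list[int]:
        """1-based inclusive residue indices of one region (or 'A+B' union)."""
        if "+" in name:
            out: list[int] = []
            for part in name.split("+"):
                out.extend(self.residues(part))
            return out
        try:
            lo, hi = self.regions[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; known: {sorted(self.regions)}"
            ) from None
        return list(range(lo, hi + 1))


def region_residues(scheme: RegionScheme, region_name: str) -> list[int]:
    """Module-level alias for :meth:`RegionScheme.residues`."""
    return scheme.residues(region_name)


class Topology:
    """Chains, residues and atoms of one or more peptide chains.

    Atom attributes are stored column-wise in numpy arrays for vectorised
    analysis. Residues are indexed 1-based within each chain; ``resid`` maps
    each atom to a 0-based global residue ordinal.
    """

    def __init__(
        self,
        chain_ids,
        residue_names,
        residue_chains,
        residue_numbers,
        atom_names,
        atom_resid,
        charges=None,
        sigmas=None,
        epsilons=None,
        born_radii=None,
        hydrophobic=None,
    ):
        self.chain_ids = list(chain_ids)
        self.residue_names = list(residue_names)
        self.residue_chains = list(residue_chains)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.atom_names = list(atom_names)
        self.atom_resid = np.asarray(atom_resid, dtype=int)
        n = len(self.atom_names)
        self.elements = np.array(
            [templates.element_of(a) for a in self.atom_names]
        )
        zeros = np.zeros(n)
        self.charges = np.asarray(charges, float) if charges is not None else zeros.copy()
        self.sigmas = np.asarray(sigmas, float) if sigmas is not None else np.array(
            [constants.LJ_PARAMS[e][0] for e in self.elements]
        )
        self.epsilons = np.asarray(epsilons, float) if epsilons is not None else np.array(
            [constants.LJ_PARAMS[e][1] for e in self.elements]
        )
        self.born_radii = np.asarray(born_radii, float) if born_radii is not None else np.array(
            [constants.BORN_RADIUS[e] for e in self.elements]
        )
        if hydrophobic is not None:
            self.hydrophobic = np.asarray(hydrophobic, bool)
        else:
            self.hydrophobic = np.array(
                [e in constants.HYDROPHOBIC_ELEMENTS for e in self.elements]
            )
        self._validate()

    # -- construction/validation -------------------------------------------

    def _validate(self):
        if self.atom_resid.size and (
            self.atom_resid.min() < 0
            or self.atom_resid.max() >= len(self.residue_names)
        ):
            raise ValueError("atom maps to a non-existent residue")
        for chain in self.chain_ids:
            nums = [
                n
                for n, c in zip(self.residue_numbers, self.residue_chains)
                if c == chain
            ]
            if nums != list(range(1, len(nums) + 1)):
                raise ValueError(
                    f"residue numbers of chain {chain!r} must be contiguous from 1"
                )
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")
        for arr, what in (
            (self.sigmas, "sigma"),
            (self.epsilons, "epsilon"),
            (self.born_radii, "Born radius"),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{what} must be non-negative")

    # -- basic sizes --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    # -- selections ---------------------------------------------------------

    def chain_residue_ordinals(self, chain_id: str) -> np.ndarray:
        """0-based global residue ordinals belonging to one chain."""
        return np.array(
            [i for i, c in enumerate(self.residue_chains) if c == chain_id],
            dtype=int,
        )

    def residue_ordinal(self, chain_id: str, resnum: int) -> int:
        """Global residue ordinal of residue `resnum` (1-based) in a chain."""
        for i, (c, n) in enumerate(
            zip(self.residue_chains, self.residue_numbers)
        ):
            if c == chain_id and n == resnum:
                return i
        raise KeyError(f"residue {resnum} not found in chain {chain_id!r}")

    def atom_indices(
        self,
        chain_id: str | None = None,
        names=None,
        residue_ordinals=None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Atom indices filtered by chain, atom name set, residues, heaviness."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            chain_res = set(self.chain_residue_ordinals(chain_id).tolist())
            mask &= np.array([r in chain_res for r in self.atom_resid])
        if names is not None:
            nameset = set(names)
            mask &= np.array([a in nameset for a in self.atom_names])
        if residue_ordinals is not None:
            rset = set(int(r) for r in residue_ordinals)
            mask &= np.array([r in rset for r in self.atom_resid])
        if heavy_only:
            mask &= self.elements != "H"
        return np.flatnonzero(mask)

    def ca_indices(self, chain_id: str | None = None) -> np.ndarray:
        return self.atom_indices(chain_id=chain_id, names=("CA",))

    def backbone_indices(self) -> dict:
        """Per-residue backbone atom indices, −1 where absent.

        Returns a dict of int arrays keyed by atom name ("N","CA","C","O","H"),
        each of length ``n_residues``.
        """
        out = {k: np.full(self.n_residues, -1, dtype=int) for k in
               ("N", "CA", "C", "O", "H")}
        for i, (name, rid) in enumerate(zip(self.atom_names, self.atom_resid)):
            if name in out and out[name][rid] == -1:
                out[name][rid] = i
        return out

    def masses(self) -> np.ndarray:
        return np.array([constants.ATOMIC_MASS[e] for e in self.elements])

    def vdw_radii(self) -> np.ndarray:
        return np.array([constants.VDW_RADIUS[e] for e in self.elements])


def build_topology(
    sequence: str,
    chain_id: str = "A",
    terminal_mode: str = "none",
    protonate_his: bool = False,
) -> Topology:
    """Build a peptide topology from a one-letter sequence.

    Heavy atoms follow the bundled residue templates; the backbone amide H is
    generated for every non-proline residue after the first (the
    DSSP-style assignment reconstructs its position from the preceding
    carbonyl). ``terminal_mode`` is "none" or "oxt" (append a C-terminal OXT).

    Raises ``ValueError`` naming the position of the first unknown residue
    code.
    """
    if terminal_mode not in ("none", "oxt"):
        raise ValueError(f"terminal_mode must be 'none' or 'oxt', got {terminal_mode!r}")
    residue_names, atom_names, atom_resid, charges = [], [], [], []
    for pos, code in enumerate(sequence, start=1):
        try:
            resname = templates.ONE_TO_THREE[code]
        except KeyError:
            raise ValueError(
                f"unknown residue code {code!r} at position {pos}"
            ) from None
        residue_names.append(resname)
        rid = pos - 1
        oxt = terminal_mode == "oxt" and pos == len(sequence)
        side_q = dict(templates.SIDECHAIN_CHARGES.get(resname, {}))
        if resname == "HIS" and protonate_his:
            side_q.update(templates.HIS_PROTONATED_CHARGES)
        has_h = pos > 1 and resname != "PRO"
        for name in templates.heavy_atom_names(resname, oxt=oxt):
            atom_names.append(name)
            atom_resid.append(rid)
            if name in templates.BACKBONE_CHARGES:
                q = templates.BACKBONE_CHARGES[name]
                if name == "N" and not has_h:
                    # N absorbs the amide-H charge so residues stay neutral
                    q += templates.BACKBONE_CHARGES["H"]
                charges.append(q)
            else:
                charges.append(side_q.get(name, 0.0))
            if name == "N" and has_h:
                atom_names.append("H")
                atom_resid.append(rid)
                charges.append(templates.BACKBONE_CHARGES["H"])
    return Topology(
        chain_ids=[chain_id],
        residue_names=residue_names,
        residue_chains=[chain_id] * len(residue_names),
        residue_numbers=list(range(1, len(residue_names) + 1)),
        atom_names=atom_names,
        atom_resid=atom_resid,
        charges=charges,
    )


def merge_topologies(a: Topology, b: Topology) -> Topology:
    """Concatenate two single- or multi-chain topologies (chains must differ)."""
    if set(a.chain_ids) & set(b.chain_ids):
        raise ValueError("chain ids overlap")
    off = a.n_residues
    return Topology(
        chain_ids=a.chain_ids + b.chain_ids,
        residue_names=a.residue_names + b.residue_names,
        residue_chains=a.residue_chains + b.residue_chains,
        residue_numbers=np.concatenate([a.residue_numbers, b.residue_numbers]),
        atom_names=a.atom_names + b.atom_names,
        atom_resid=np.concatenate([a.atom_resid, b.atom_resid + off]),
        charges=np.concatenate([a.charges, b.charges]),
        sigmas=np.concatenate([a.sigmas, b.sigmas]),
        epsilons=np.concatenate([a.epsilons, b.epsilons]),
        born_radii=np.concatenate([a.born_radii, b.born_radii]),
        hydrophobic=np.concatenate([a.hydrophobic, b.hydrophobic]),
    )


@dataclass
class Ensemble:
    """Ordered coordinate frames over a fixed topology.

    coords: (n_frames, n_atoms, 3) nm. times: ps. replicas: int ids (−1 =
    unset). temperatures: K (NaN = unset). weights: optional per-frame weights.
    """

    topology: Topology
    coords: np.ndarray
    times: np.ndarray | None = None
    replicas: np.ndarray | None = None
    temperatures: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.n_frames
        if self.times is None:
            self.times = np.arange(n, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
        if self.replicas is None:
            self.replicas = np.full(n, -1, dtype=int)
        else:
            self.replicas = np.asarray(self.replicas, dtype=int)
        if self.temperatures is None:
            self.temperatures = np.full(n, np.nan)
        else:
            self.temperatures = np.asarray(self.temperatures, dtype=float)
        for arr, what in (
            (self.times, "times"),
            (self.replicas, "replicas"),
            (self.temperatures, "temperatures"),
        ):
            if len(arr) != n:
                raise ValueError(f"{what} length does not match frame count")
        for rep in np.unique(self.replicas):
            t = self.times[self.replicas == rep]
            if np.any(np.diff(t) < 0):
                raise ValueError(
                    f"times must be non-decreasing within replica {rep}"
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def subset(self, frame_indices) -> "Ensemble":
        idx = np.asarray(frame_indices, dtype=int)
        return Ensemble(
            topology=self.topology,
            coords=self.coords[idx],
            times=self.times[idx],
            replicas=self.replicas[idx],
            temperatures=self.temperatures[idx],
            weights=None if self.weights is None else self.weights[idx],
        )


def select_production(
    ensemble: Ensemble,
    start: float,
    end: float,
    stride: float,
    replica_ids=None,
) -> Ensemble:
    """Select the production window (start, end] ps at a given stride.

    Retains frames at times start + k·stride (k ≥ 1) from the listed replicas
    (all replicas when ``replica_ids`` is None). The window is half-open on
    the left so a 140 ns window at 50 ps yields exactly 2,800 frames per
    replica. The stride must be a multiple of the source sampling interval.
    """
    if not start < end:
        raise ValueError("start must be < end")
    if stride <= 0:
        raise ValueError("stride must be positive")
    reps = (
        np.unique(ensemble.replicas)
        if replica_ids is None
        else np.asarray(list(replica_ids))
    )
    keep: list[int] = []
    for rep in reps:
        idx = np.flatnonzero(ensemble.replicas == rep)
        t = ensemble.times[idx]
        if len(t) > 1:
            dt = np.diff(np.unique(t))
            src = dt.min() if dt.size else stride
            if src > 0 and abs(stride / src - round(stride / src)) > 1e-9:
                raise ValueError(
                    f"stride {stride} ps is not a multiple of the source "
                    f"sampling interval {src} ps (replica {rep})"
                )
        phase = np.mod(t - start, stride)
        on_grid = (np.abs(phase) < 1e-6) | (np.abs(phase - stride) < 1e-6)
        mask = (t > start) & (t <= end) & on_grid
        keep.extend(idx[mask].tolist())
    if not keep:
        warnings.warn(
            f"production window ({start}, {end}] ps selected no frames",
            stacklevel=2,
        )
        return ensemble.subset([])
    return ensemble.subset(sorted(keep))


def total_sampled_time_us(n_replicas: int, replica_length_ns: float) -> float:
    """Aggregate sampling of an REMD configuration, in μs."""
    return n_replicas * replica_length_ns / 1000.0
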