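"""Synthetic inputs: temperature ladders, a toy replica-exchange sampler,
and a state-mixture ensemble generator with planted ground truth.

The mixture generator is the workhorse for closed-loop validation: it draws
a conformational state per frame, builds ideal-geometry backbone templates
for that state (helices, paired β-strands with proper hydrogen-bond
register, collapsed or extended coil), plants salt bridges and interchain
contacts with prescribed probabilities, adds Gaussian coordinate noise and a
random rigid motion, and returns the ground truth so that downstream
analyses can be checked for parameter recovery.

Strand plantings are realised only through hydrogen-bonded pairings (a lone
extended segment has no bridge partners and no strand assignment); the
per-frame true secondary-structure labels are therefore the assignment of
the noise-free template, computed once per template and cached.

The toy replica-exchange sampler is a bead-chain Metropolis Monte Carlo
walker on a temperature ladder. Its fidelity target is statistical structure
(multi-replica, time-correlated, temperature-dependent occupancies), not
atomistic physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import builder
from .constants import KB
from .core import Ensemble, Topology, build_topology, merge_topologies
from .secstruct import assign_ss_ensemble


# ---------------------------------------------------------------------------
# temperature ladder and exchange
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LadderSpec:
    """Geometric (exponentially spaced) replica temperature ladder."""

    t_min: float = 276.0
    t_max: float = 592.3
    n_replicas: int = 64

    def __post_init__(self):
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")


def geometric_ladder(spec: LadderSpec) -> np.ndarray:
    """T_k = t_min·(t_max/t_min)^(k/(n−1)); endpoints exact."""
    k = np.arange(spec.n_replicas)
    t = spec.t_min * (spec.t_max / spec.t_min) ** (k / (spec.n_replicas - 1))
    t[0], t[-1] = spec.t_min, spec.t_max
    return t


def swap_acceptance(t_i: float, t_j: float, e_i: float, e_j: float) -> float:
    """Metropolis acceptance for exchanging configurations between replicas."""
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    if not (np.isfinite(e_i) and np.isfinite(e_j)):
        raise ValueError("energies must be finite")
    delta = (1.0 / (KB * t_i) - 1.0 / (KB * t_j)) * (e_i - e_j)
    return float(min(1.0, np.exp(min(delta, 0.0)) if delta < 0 else 1.0))


# ---------------------------------------------------------------------------
# toy bead-chain REMD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    """Bead-chain model: harmonic bonds, dihedral bias, Go-style wells."""

    n_beads: int = 12
    bond_length: float = 0.38  # nm, Cα virtual bond
    spring_k: float = 1000.0  # kcal/mol/nm²
    #: (force constant kcal/mol, preferred dihedral degrees) applied to every
    #: bead quadruple as k·(1 − cos(φ − φ0))
    dihedral_terms: tuple = ()
    #: (i, j, depth kcal/mol, r_well nm) square wells between bead pairs
    contact_wells: tuple = ()
    step_size: float = 0.03  # nm, Gaussian single-bead move

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("need at least 2 beads")
        if self.spring_k < 0 or any(k < 0 for k, _ in self.dihedral_terms):
            raise ValueError("force constants must be non-negative")
        for i, j, depth, r in self.contact_wells:
            if not (0 <= i < self.n_beads and 0 <= j < self.n_beads):
                raise ValueError("contact well indices out of range")
            if depth < 0 or r <= 0:
                raise ValueError("well depth/radius must be positive")


def toy_chain_topology(n_beads: int, chain_id: str = "A") -> Topology:
    """Cα-bead topology (one GLY-named residue with a single CA per bead)."""
    return Topology(
        chain_ids=[chain_id],
        residue_names=["GLY"] * n_beads,
        residue_chains=[chain_id] * n_beads,
        residue_numbers=list(range(1, n_beads + 1)),
        atom_names=["CA"] * n_beads,
        atom_resid=list(range(n_beads)),
    )


def _dihedral(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return np.arctan2(np.dot(m1, n2), np.dot(n1, n2))


class _ToyEnergy:
    def __init__(self, spec: ToyModelSpec):
        self.spec = spec

    def bond_energy(self, x, bonds):
        s = self.spec
        total = 0.0
        for i in bonds:
            r = np.linalg.norm(x[i + 1] - x[i])
            total += 0.5 * s.spring_k * (r - s.bond_length) ** 2
        return total

    def local(self, x, moved: int) -> float:
        """Energy of all terms touching one bead."""
        s = self.spec
        n = s.n_beads
        e = self.bond_energy(
            x, [b for b in (moved - 1, moved) if 0 <= b < n - 1]
        )
        for k, phi0 in s.dihedral_terms:
            for q in range(max(0, moved - 3), min(moved + 1, n - 3)):
                phi = _dihedral(x[q], x[q + 1], x[q + 2], x[q + 3])
                e += k * (1.0 - np.cos(phi - np.deg2rad(phi0)))
        for i, j, depth, r_well in s.contact_wells:
            if moved in (i, j):
                if np.linalg.norm(x[i] - x[j]) < r_well:
                    e -= depth
        return e

    def total(self, x) -> float:
        s = self.spec
        n = s.n_beads
        e = self.bond_energy(x, range(n - 1))
        for k, phi0 in s.dihedral_terms:
            for q in range(n - 3):
                phi = _dihedral(x[q], x[q + 1], x[q + 2], x[q + 3])
                e += k * (1.0 - np.cos(phi - np.deg2rad(phi0)))
        for i, j, depth, r_well in s.contact_wells:
            if np.linalg.norm(x[i] - x[j]) < r_well:
                e -= depth
        return e


def run_toy_remd(
    model: ToyModelSpec,
    ladder: LadderSpec,
    n_steps: int,
    exchange_interval: int = 50,
    seed: int = 0,
    sample_interval: int | None = None,
) -> Ensemble:
    """Bead-chain Metropolis MC on a temperature ladder with neighbour swaps.

    One "step" is one attempted single-bead move per replica. Neighbour
    exchanges are attempted every ``exchange_interval`` steps (alternating
    even/odd pairs); frames are recorded every ``sample_interval`` steps
    (default: the exchange interval) with pseudo-time 1 ps per step.
    Deterministic under a fixed seed.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if exchange_interval <= 0:
        raise ValueError("exchange interval must be positive")
    sample_interval = sample_interval or exchange_interval
    temps = geometric_ladder(ladder)
    n_rep = len(temps)
    rng = np.random.default_rng(seed)
    energy = _ToyEnergy(model)
    n = model.n_beads
    # initial chains: straight lines, one per replica
    configs = [
        np.outer(np.arange(n), np.array([model.bond_length, 0.0, 0.0]))
        for _ in range(n_rep)
    ]
    e_tot = [energy.total(x) for x in configs]
    frames, times, reps, ftemps = [], [], [], []
    swap_parity = 0
    for step in range(1, n_steps + 1):
        for r in range(n_rep):
            beta = 1.0 / (KB * temps[r])
            x = configs[r]
            bead = int(rng.integers(n))
            old = x[bead].copy()
            e_old = energy.local(x, bead)
            x[bead] = old + rng.normal(0.0, model.step_size, 3)
            e_new = energy.local(x, bead)
            de = e_new - e_old
            if de <= 0 or rng.random() < np.exp(-beta * de):
                e_tot[r] += de
            else:
                x[bead] = old
        if step % exchange_interval == 0:
            for lo in range(swap_parity, n_rep - 1, 2):
                p = swap_acceptance(
                    temps[lo], temps[lo + 1], e_tot[lo], e_tot[lo + 1]
                )
                if rng.random() < p:
                    configs[lo], configs[lo + 1] = configs[lo + 1], configs[lo]
                    e_tot[lo], e_tot[lo + 1] = e_tot[lo + 1], e_tot[lo]
            swap_parity = 1 - swap_parity
        if step % sample_interval == 0:
            for r in range(n_rep):
                frames.append(configs[r].copy())
                times.append(float(step))
                reps.append(r)
                ftemps.append(temps[r])
    top = toy_chain_topology(n)
    return Ensemble(
        topology=top,
        coords=np.array(frames),
        times=np.array(times),
        replicas=np.array(reps),
        temperatures=np.array(ftemps),
    )


def reconstruct_backbone_ensemble(toy: Ensemble) -> Ensemble:
    """Rebuild an approximate poly-GLY backbone from a Cα-bead ensemble.

    Lets hydrogen-bond-based secondary-structure assignment run on toy
    Monte-Carlo frames.
    """
    n = toy.topology.n_residues
    top = build_topology("G" * n, chain_id=toy.topology.chain_ids[0])
    coords = np.empty((toy.n_frames, top.n_atoms, 3))
    for f in range(toy.n_frames):
        bb = builder.backbone_from_ca(toy.coords[f])
        coords[f] = builder.assemble_coords(top, bb)
    return Ensemble(
        topology=top,
        coords=coords,
        times=toy.times,
        replicas=toy.replicas,
        temperatures=toy.temperatures,
    )


# ---------------------------------------------------------------------------
# state-mixture generator
# ---------------------------------------------------------------------------

#: structural motifs the template factory can realise, with the approximate
#: (nbeta, ncontact) level each produces on the default 42-mer regions
MOTIFS = (
    "coil",          # fully disordered             → (0.00, 0)
    "helix",         # NTR/CHC helix, rest coil     → (0.00, 0)
    "collapsed",     # CTR packed on CHC, no register → (0.00, high)
    "bridge1",       # single CHC–CTR bridge pair   → (0.11, low)
    "pair2",         # short CHC–CTR ladder         → (0.33, mid)
    "hairpin3",      # full CHC–CTR hairpin ladder  → (0.56, high)
    "ctr_hairpin",   # hairpin internal to the CTR  → (0.33, 0)
    "atypical",      # preCHC–CHC sheet + CTR hairpin → (0.50, 0)
)


@dataclass(frozen=True)
class StateSpec:
    """One planted conformational state.

    ``motif`` picks the structural template; the regional strand/helix
    probabilities and the CHC–CTR contact probability describe the state and
    are used to derive the motif when ``motif`` is None (strand in CHC and
    CTR with a contact → hairpin ladder, without → atypical sheet, CTR-only
    strand → CTR hairpin, contact without strand → collapsed, helix → helix,
    else coil).
    """

    label: str
    fraction: float
    region_strand: dict = field(default_factory=dict)
    region_helix: dict = field(default_factory=dict)
    contact_prob: float = 0.0
    noise_sd: float = 0.005  # nm
    motif: str | None = None

    def __post_init__(self):
        probs = [self.fraction, self.contact_prob]
        probs += list(self.region_strand.values())
        probs += list(self.region_helix.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.motif is not None and self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")

    def draw_motif(self, rng: np.random.Generator) -> str:
        if self.motif is not None:
            return self.motif
        chc = rng.random() < self.region_strand.get("CHC", 0.0)
        ctr = rng.random() < self.region_strand.get("CTR", 0.0)
        contact = rng.random() < self.contact_prob
        if chc and ctr:
            return "hairpin3" if contact else "atypical"
        if ctr:
            return "ctr_hairpin"
        if chc:
            return "bridge1"
        if contact:
            return "collapsed"
        if rng.random() < self.region_helix.get("NTR", 0.0) or rng.random() < \
                self.region_helix.get("CHC", 0.0):
            return "helix"
        return "coil"


@dataclass(frozen=True)
class StateMixtureSpec:
    """A mixture of planted states with optional salt-bridge planting."""

    states: tuple
    n_frames: int
    seed: int = 0
    salt_bridge_prob: float | None = None
    dt_ps: float = 1.0

    def __post_init__(self):
        total = sum(s.fraction for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, not 1")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")


@dataclass
class MixtureTruth:
    """Ground truth returned alongside a generated mixture ensemble."""

    state_labels: np.ndarray  # (F,) state label strings
    motifs: np.ndarray  # (F,) motif names
    ss_labels: np.ndarray  # (F, R) five-class integer codes
    salt_bridge: np.ndarray | None  # (F,) bool, None if not planted

    def state_fractions(self) -> dict:
        labels, counts = np.unique(self.state_labels, return_counts=True)
        return dict(zip(labels.tolist(), (counts / len(self.state_labels)).tolist()))


# -- template construction --------------------------------------------------

_STRAND = builder.PHI_PSI["strand"]
_HELIX = builder.PHI_PSI["helix"]
_PPII = builder.PHI_PSI["ppii"]


def _rigid(params, pts):
    rot = Rotation.from_rotvec(params[:3])
    return rot.apply(pts) + params[3:]


def _fit_segment(local_pts: dict, targets: list, seed: int = 0) -> np.ndarray:
    """Find the rigid placement of a segment matching distance targets.

    ``local_pts`` maps point names to local coordinates; ``targets`` is a
    list of (name, fixed_point, distance). Returns the 6-vector (rotvec,
    translation); several deterministic restarts guard against local minima.
    """
    names = [t[0] for t in targets]
    mobile = np.array([local_pts[n] for n in names])
    fixed = np.array([t[1] for t in targets])
    dists = np.array([t[2] for t in targets])
    exact = dists == 0.0  # point-match targets contribute vector residuals

    def resid(params):
        placed = _rigid(params, mobile)
        scalar = np.linalg.norm(placed - fixed, axis=1) - dists
        parts = [scalar[~exact]]
        if exact.any():
            parts.append((placed[exact] - fixed[exact]).ravel())
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for trial in range(8):
        rotvec = rng.normal(0.0, 1.5, 3) if trial else np.zeros(3)
        shift = fixed.mean(axis=0) - Rotation.from_rotvec(rotvec).apply(
            mobile
        ).mean(axis=0)
        sol = least_squares(resid, np.concatenate([rotvec, shift]))
        if sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    return best


def _segment_bb(phi_psi_list):
    phi = [p for p, _ in phi_psi_list]
    psi = [p for _, p in phi_psi_list]
    return builder.build_backbone(phi, psi)


def _apply_rigid(bb: dict, params) -> dict:
    return {
        k: (_rigid(params, v) if not np.any(np.isnan(v)) else
            np.where(np.isnan(v), v, _rigid(params, np.nan_to_num(v))))
        for k, v in bb.items()
    }


def _place_far(bb: dict, offset) -> dict:
    return {k: v + np.asarray(offset, float) for k, v in bb.items()}


class TemplateFactory:
    """Builds and caches noise-free 42-mer (+hexapeptide) templates.

    Templates are constructed from ideal-geometry segments; β-ladders are
    realised by rigidly fitting one strand segment so that the alternating
    double hydrogen bonds of an antiparallel sheet form with proper register.
    Chain breaks between segments are tolerated (the analyses are
    hydrogen-bond- and distance-based); amide hydrogens are recomputed
    globally with the anti-to-carbonyl convention after assembly.
    """

    #: double-hydrogen-bonded pairs per ladder motif (1-based residues)
    LADDER_DOUBLES = {
        "bridge1": [(17, 42)],
        "pair2": [(17, 40), (19, 38)],
        "hairpin3": [(17, 38), (19, 36), (21, 34)],
    }
    #: CTR strand extent per ladder motif (1-based, inclusive)
    LADDER_CTR_STRAND = {
        "bridge1": (41, 42),
        "pair2": (37, 41),
        "hairpin3": (33, 39),
    }

    def __init__(self, topology: Topology, hexapeptide: bool):
        self.top = topology
        self.hex = hexapeptide
        self._cache: dict = {}

    # -- segment dihedral recipes ------------------------------------------

    def _chain_a_angles(self, motif: str, ntr: str):
        """(φ, ψ) for residues 1..21 (or 1..29 for unsegmented motifs)."""
        angles = []
        for r in range(1, 22):
            if 2 <= r <= 15 and ntr == "helix":
                angles.append(_HELIX)
            elif motif == "helix" and 12 <= r <= 21:
                angles.append(_HELIX)
            elif 17 <= r <= 21 and motif in self.LADDER_DOUBLES:
                angles.append(_STRAND)
            elif motif == "atypical" and 17 <= r <= 21:
                angles.append(_STRAND)
            else:
                angles.append(_PPII)
        return angles

    def _segment(self, residues, angle_of):
        """Build a backbone segment for 1-based residues [lo, hi]."""
        lo, hi = residues
        return _segment_bb([angle_of(r) for r in range(lo, hi + 1)])

    def _ladder_fit(self, bb_fixed, bb_mobile, doubles, lo_mobile, lo_fixed=1,
                    seed=0):
        """Place a mobile strand so the listed double H-bond pairs form."""
        # target positions for the mobile strand's N/H/O are laid out along
        # the fixed strand's carbonyl and N–H directions, which makes the
        # rigid fit essentially convex
        targets = []
        local = {}
        hi_fixed = lo_fixed + len(bb_fixed["CA"]) - 1
        for i, j in doubles:
            jj = j - lo_mobile
            ii = i - lo_fixed
            u_co = bb_fixed["O"][ii] - bb_fixed["C"][ii]
            u_co /= np.linalg.norm(u_co)
            u_nh = bb_fixed["H"][ii] - bb_fixed["N"][ii]
            u_nh /= np.linalg.norm(u_nh)
            local[f"N{j}"] = bb_mobile["N"][jj]
            local[f"H{j}"] = bb_mobile["H"][jj]
            local[f"O{j}"] = bb_mobile["O"][jj]
            targets += [
                (f"N{j}", bb_fixed["O"][ii] + 2.9 * u_co, 0.0),
                (f"H{j}", bb_fixed["O"][ii] + 1.9 * u_co, 0.0),
                (f"O{j}", bb_fixed["H"][ii] + 1.9 * u_nh, 0.0),
            ]
        if len(doubles) == 1:
            # anchor the register for the under-determined single-pair fit
            i, j = doubles[0]
            for di in (1, 2):
                jj = j - di - lo_mobile
                if jj >= 0 and i + di <= hi_fixed:
                    local[f"CA{j - di}"] = bb_mobile["CA"][jj]
                    targets.append(
                        (f"CA{j - di}", bb_fixed["CA"][i + di - lo_fixed], 5.2)
                    )
        params = _fit_segment(local, targets, seed=seed)
        return _apply_rigid(bb_mobile, params)

    # -- motif assembly -----------------------------------------------------

    def _build_42mer(self, motif: str, ntr: str):
        """Backbone dict (42 residues, Å) for one motif."""
        if motif in self.LADDER_DOUBLES:
            return self._build_ladder(motif, ntr)
        if motif == "atypical":
            return self._build_atypical()
        if motif == "ctr_hairpin":
            return self._build_ctr_hairpin(ntr, offset=(30.0, 18.0, 0.0))
        return self._build_simple(motif, ntr)

    def _build_simple(self, motif: str, ntr: str):
        def angle_of(r):
            if 2 <= r <= 15 and ntr == "helix":
                return _HELIX
            if motif == "helix" and 12 <= r <= 21:
                return _HELIX
            return _PPII

        bb_a = self._segment((1, 29), angle_of)
        bb_b = self._segment((30, 42), lambda r: _STRAND)
        if motif == "collapsed":
            # CTR laid across the CHC, perpendicular, Cα–Cα ≈ 5.5 Å, no
            # backbone hydrogen-bond register
            chc_ca = bb_a["CA"][16:21]
            center = chc_ca.mean(axis=0)
            axis = chc_ca[-1] - chc_ca[0]
            axis /= np.linalg.norm(axis)
            ref = np.array([0.0, 0.0, 1.0])
            perp = np.cross(axis, ref)
            perp /= np.linalg.norm(perp)
            targets = []
            local = {}
            for k, j in enumerate((33, 36, 39)):
                local[f"CA{j}"] = bb_b["CA"][j - 30]
                goal = center + 5.5 * perp + (k - 1) * 4.5 * ref
                targets.append((f"CA{j}", goal, 0.0))
            local["CA31"] = bb_b["CA"][1]
            targets.append(("CA31", center + 5.5 * perp - 9.0 * ref, 0.0))
            params = _fit_segment(local, targets)
            bb_b = _apply_rigid(bb_b, params)
        else:
            bb_b = _place_far(bb_b, (40.0, 25.0, 0.0))
        return self._concat((bb_a, 29), (bb_b, 13))

    def _build_ladder(self, motif: str, ntr: str):
        bb_a = self._segment((1, 21), lambda r: self._chain_a_angles(motif, ntr)[r - 1])
        lo_s, hi_s = self.LADDER_CTR_STRAND[motif]

        def angle_b(r):
            if lo_s <= r <= hi_s:
                return _STRAND
            # coil the pre-strand tail into a helix for the short-ladder
            # motifs so the extended remainder cannot ladder up against the
            # CHC beyond the intended pairs
            if motif in ("bridge1", "pair2") and r < lo_s:
                return _HELIX
            return _PPII

        bb_b = self._segment((22, 42), angle_b)
        bb_b = self._ladder_fit(
            bb_a, bb_b, self.LADDER_DOUBLES[motif], lo_mobile=22
        )
        return self._concat((bb_a, 21), (bb_b, 21))

    def _build_ctr_hairpin(self, ntr: str, offset):
        def angle_of(r):
            return _HELIX if (2 <= r <= 15 and ntr == "helix") else _PPII

        bb_a = self._segment((1, 29), angle_of)
        bb_b1 = self._segment((30, 37), lambda r: _STRAND if r <= 34 else _PPII)
        bb_b2 = self._segment((38, 42), lambda r: _STRAND)
        bb_b2 = self._ladder_fit(
            bb_b1, bb_b2, [(31, 41), (33, 39)], lo_mobile=38, lo_fixed=30
        )
        hairpin = self._concat((bb_b1, 8), (bb_b2, 5))
        hairpin = _place_far(hairpin, offset)
        return self._concat((bb_a, 29), (hairpin, 13))

    def _build_atypical(self):
        bb_a1 = self._segment(
            (1, 16), lambda r: _STRAND if 9 <= r <= 13 else _PPII
        )
        bb_a2 = self._segment(
            (17, 29), lambda r: _STRAND if r <= 21 else _PPII
        )
        bb_a2 = self._ladder_fit(
            bb_a1, bb_a2, [(12, 19), (10, 21)], lo_mobile=17
        )
        head = self._concat((bb_a1, 16), (bb_a2, 13))
        bb_b1 = self._segment((30, 37), lambda r: _STRAND if r <= 34 else _PPII)
        bb_b2 = self._segment((38, 42), lambda r: _STRAND)
        bb_b2 = self._ladder_fit(bb_b1, bb_b2, [(31, 41), (33, 39)], lo_mobile=38, lo_fixed=30)
        tail = self._concat((bb_b1, 8), (bb_b2, 5))
        tail = _place_far(tail, (35.0, 22.0, 0.0))
        return self._concat((head, 29), (tail, 13))

    @staticmethod
    def _concat(*segments):
        out = {}
        for key in ("N", "CA", "C", "O", "H"):
            out[key] = np.concatenate([bb[key][:n] for bb, n in segments])
        return out

    def _assemble(self, motif: str, ntr: str):
        bb = self._build_42mer(motif, ntr)
        n_res_a = 42
        # recompute all amide hydrogens with the anti-to-carbonyl convention,
        # including across segment junctions, so stored H equals what the
        # assigner would reconstruct
        for i in range(1, n_res_a):
            bb["H"][i] = builder.amide_h(bb["N"][i], bb["C"][i - 1], bb["O"][i - 1])
        if self.hex:
            hex_bb = _segment_bb([_PPII] * 6)
            local = {f"CA{r}": hex_bb["CA"][r - 1] for r in range(1, 6)}
            targets = [
                (f"CA{r}", bb["CA"][r + 1], 5.5) for r in range(1, 6)
            ]
            params = _fit_segment(local, targets)
            hex_bb = _apply_rigid(hex_bb, params)
            for i in range(1, 6):
                hex_bb["H"][i] = builder.amide_h(
                    hex_bb["N"][i], hex_bb["C"][i - 1], hex_bb["O"][i - 1]
                )
            full = {
                k: np.concatenate([bb[k], hex_bb[k]]) for k in bb
            }
        else:
            full = bb
        coords = builder.assemble_coords(self.top, full)
        if self.hex:
            coords = self._declash_interchain(coords)
        labels = assign_ss_ensemble(
            Ensemble(topology=self.top, coords=coords[None])
        )[0]
        return coords, labels

    def _declash_interchain(self, coords, min_dist=0.30):
        """Push hexapeptide side-chain atoms out of steric overlap.

        The schematic side chains can interpenetrate across the interface;
        overlaps below ``min_dist`` nm are resolved by moving the
        hexapeptide atom outward along the pair axis (backbone atoms of
        either chain are never moved, preserving hydrogen-bond geometry).
        """
        bb_names = {"N", "CA", "C", "O", "H"}
        a_idx = self.top.atom_indices(chain_id="A")
        b_idx = self.top.atom_indices(chain_id="B")
        is_side = np.array(
            [name not in bb_names for name in self.top.atom_names]
        )
        for _ in range(40):
            d = coords[b_idx][:, None, :] - coords[a_idx][None, :, :]
            dist = np.linalg.norm(d, axis=-1)
            bi, ai = np.nonzero(dist < min_dist)
            if bi.size == 0:
                break
            for b, a in zip(bi, ai):
                gb, ga = b_idx[b], a_idx[a]
                axis = d[b, a]
                n = np.linalg.norm(axis)
                axis = axis / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
                push = (min_dist - n + 0.02)
                # move a side-chain atom, never backbone (preserves the
                # hydrogen-bond geometry the templates were fitted for)
                if is_side[gb]:
                    coords[gb] += push * axis
                elif is_side[ga]:
                    coords[ga] -= push * axis
                else:
                    coords[gb] += push * axis  # backbone–backbone: move hex
        return coords

    def get(self, motif: str, ntr: str = "coil"):
        if motif in ("atypical",):
            ntr = "coil"  # preCHC strand precludes the NTR helix
        key = (motif, ntr)
        if key not in self._cache:
            self._cache[key] = self._assemble(motif, ntr)
        return self._cache[key]


def mixture_topology(
    sequence: str | None = None,
    hexapeptide: str | None = None,
) -> Topology:
    """Topology for the 42-mer (chain A) plus an optional hexapeptide (B)."""
    from .core import ABETA42_SEQUENCE, HEXAPEPTIDES

    top = build_topology(sequence or ABETA42_SEQUENCE, chain_id="A")
    if hexapeptide is not None:
        seq = HEXAPEPTIDES.get(hexapeptide, hexapeptide)
        top = merge_topologies(top, build_topology(seq, chain_id="B"))
    return top


def sample_mixture_ensemble(
    spec: StateMixtureSpec, topology: Topology
) -> tuple[Ensemble, MixtureTruth]:
    """Generate a mixture ensemble with planted per-frame ground truth."""
    rng = np.random.default_rng(spec.seed)
    hexapeptide = len(topology.chain_ids) > 1
    factory = TemplateFactory(topology, hexapeptide)
    fractions = np.array([s.fraction for s in spec.states])
    draws = rng.choice(len(spec.states), size=spec.n_frames, p=fractions)
    n_res = topology.n_residues

    d23 = topology.residue_ordinal("A", 23)
    k28 = topology.residue_ordinal("A", 28)
    od1 = topology.atom_indices(residue_ordinals=[d23], names=("OD1",))
    nz = topology.atom_indices(residue_ordinals=[k28], names=("NZ",))
    plant_sb = spec.salt_bridge_prob is not None and od1.size and nz.size

    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    ss_truth = np.empty((spec.n_frames, n_res), dtype=np.int8)
    motifs = np.empty(spec.n_frames, dtype=object)
    state_labels = np.empty(spec.n_frames, dtype=object)
    sb_truth = np.zeros(spec.n_frames, bool) if plant_sb else None
    for f in range(spec.n_frames):
        state = spec.states[draws[f]]
        motif = state.draw_motif(rng)
        ntr = "helix" if rng.random() < state.region_helix.get("NTR", 0.0) else "coil"
        template, labels = factory.get(motif, ntr)
        x = template.copy()
        if plant_sb:
            bridged = rng.random() < spec.salt_bridge_prob
            sb_truth[f] = bridged
            anchor = x[od1[0]]
            direction = x[nz[0]] - anchor
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            x[nz[0]] = anchor + (0.30 if bridged else 0.80) * direction
        x = x + rng.normal(0.0, state.noise_sd, x.shape)
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        x = rot.apply(x) + rng.normal(0.0, 1.0, 3)
        coords[f] = x
        ss_truth[f] = labels
        motifs[f] = motif
        state_labels[f] = state.label
    ens = Ensemble(
        topology=topology,
        coords=coords,
        times=np.arange(spec.n_frames) * spec.dt_ps,
        replicas=np.zeros(spec.n_frames, int),
    )
    return ens, MixtureTruth(state_labels, motifs, ss_truth, sb_truth)


#: Planted mixture mirroring the free-monomer state-population structure
#: (S1..S6 plus an atypical remainder); fractions follow the published
#: free-ensemble table.
FREE_MONOMER_STATES = (
    StateSpec("S1", 0.116, motif="coil"),
    StateSpec("S2", 0.064, motif="collapsed", contact_prob=1.0),
    StateSpec("S3", 0.026, motif="bridge1",
              region_strand={"CHC": 1.0}, contact_prob=1.0),
    StateSpec("S4", 0.133, motif="ctr_hairpin", region_strand={"CTR": 1.0}),
    StateSpec("S5", 0.057, motif="pair2",
              region_strand={"CHC": 1.0, "CTR": 1.0}, contact_prob=1.0),
    StateSpec("S6", 0.470, motif="hairpin3",
              region_strand={"CHC": 1.0, "CTR": 1.0}, contact_prob=1.0),
    StateSpec("Others", 0.134, motif="atypical",
              region_strand={"CHC": 1.0, "CTR": 1.0}),
)

#: Bound-system analog: hairpin states suppressed, helix/coil enhanced
BOUND_STATES = (
    StateSpec("S1", 0.25, motif="coil"),
    StateSpec("S2", 0.13, motif="collapsed", contact_prob=1.0),
    StateSpec("S3", 0.08, motif="bridge1", contact_prob=1.0),
    StateSpec("S4", 0.17, motif="ctr_hairpin", region_strand={"CTR": 1.0}),
    StateSpec("S5", 0.08, motif="pair2", contact_prob=1.0),
    StateSpec("S6", 0.21, motif="hairpin3",
              region_strand={"CHC": 1.0, "CTR": 1.0}, contact_prob=1.0),
    StateSpec("Others", 0.08, motif="atypical",
              region_strand={"CHC": 1.0, "CTR": 1.0}),
)


# ---------------------------------------------------------------------------
# toy topologies for energetics fixtures
# ---------------------------------------------------------------------------

def synthetic_topology(
    n_residues: int,
    charge_pattern: str | np.ndarray = "neutral",
    seed: int = 0,
):
    """Toy single-bead-per-residue chain with valid energetics parameters.

    ``charge_pattern`` is "neutral" (all zero), "dipolar" (alternating ±0.5,
    net zero), or an explicit per-residue charge array. Returns (Topology,
    parameter table DataFrame). Deterministic for a fixed seed.
    """
    from .io import parameter_frame

    if n_residues < 1:
        raise ValueError("need at least one residue")
    if isinstance(charge_pattern, str):
        if charge_pattern == "neutral":
            q = np.zeros(n_residues)
        elif charge_pattern == "dipolar":
            if n_residues % 2:
                raise ValueError("dipolar pattern needs an even residue count")
            q = np.where(np.arange(n_residues) % 2 == 0, 0.5, -0.5)
        else:
            raise ValueError(f"unknown charge pattern {charge_pattern!r}")
    else:
        q = np.asarray(charge_pattern, float)
        if len(q) != n_residues:
            raise ValueError("charge array length mismatch")
    rng = np.random.default_rng(seed)
    top = Topology(
        chain_ids=["A"],
        residue_names=["GLY"] * n_residues,
        residue_chains=["A"] * n_residues,
        residue_numbers=list(range(1, n_residues + 1)),
        atom_names=["CA"] * n_residues,
        atom_resid=list(range(n_residues)),
        charges=q,
        sigmas=np.full(n_residues, 0.34) + rng.uniform(-0.01, 0.01, n_residues),
        epsilons=np.full(n_residues, 0.10) + rng.uniform(-0.005, 0.005, n_residues),
        born_radii=np.full(n_residues, 0.20) + rng.uniform(-0.01, 0.01, n_residues),
    )
    return top, parameter_frame(top)
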