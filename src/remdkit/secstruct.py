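"""Hydrogen-bond-based secondary-structure assignment and propensity profiles.

The assigner follows the Kabsch–Sander electrostatic hydrogen-bond model and
pattern rules: i→i+4 bonded turns give α-helix, i→i+3 give 3₁₀, bridge/ladder
patterns (parallel and antiparallel) give strand, hydrogen-bonded turns and
bends give turn. Eight-class bookkeeping is folded to the five classes used
throughout the package: H→ALPHA, G→THREE10, E and isolated bridge B→STRAND,
T and bend S→TURN, remainder→COIL.

Amide hydrogens are taken from the frame when the topology carries them and
reconstructed 1.01 Å from N anti to the preceding carbonyl otherwise.
Helical patterns never span chain breaks; bridges may (inter-chain sheets).
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import DSSP_Q, HBOND_ENERGY_CUTOFF
from .core import Ensemble, Topology

#: five-class labels and their one-character codes
CLASSES = ("ALPHA", "THREE10", "STRAND", "TURN", "COIL")
CODES = "HGETC"
_CODE_INDEX = {c: i for i, c in enumerate(CODES)}

_MIN_DIST_NM = 0.05  # clash guard, 0.5 Å


def hbond_energy(n, h, c, o) -> float:
    """Kabsch–Sander hydrogen-bond energy (kcal/mol) for one N-H···O=C pair.

    Positions in nm; distances enter the formula in Å. Any interatomic
    distance below 0.5 Å returns +inf (clash guard).
    """
    n, h, c, o = (np.asarray(x, float) for x in (n, h, c, o))
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST_NM:
        return np.inf
    # nm → Å: 1/r picks up a factor 0.1
    return DSSP_Q * 0.1 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


class _BackboneCache:
    """Per-topology arrays the assigner needs, computed once per ensemble."""

    def __init__(self, topology: Topology):
        self.top = topology
        self.bb = topology.backbone_indices()
        self.n_res = topology.n_residues
        self.chain_index = np.array(
            [topology.chain_ids.index(c) for c in topology.residue_chains]
        )
        self.complete = (
            (self.bb["N"] >= 0) & (self.bb["CA"] >= 0)
            & (self.bb["C"] >= 0) & (self.bb["O"] >= 0)
        )
        prev_same_chain = np.zeros(self.n_res, bool)
        prev_same_chain[1:] = self.chain_index[1:] == self.chain_index[:-1]
        self.prev_same_chain = prev_same_chain
        self.is_pro = np.array(
            [name == "PRO" for name in topology.residue_names]
        )


def _hbond_sets(coords: np.ndarray, cache: _BackboneCache) -> np.ndarray:
    """Boolean donor×acceptor hydrogen-bond matrix for a batch of frames.

    coords: (F, n_atoms, 3). Keeps at most the two lowest-energy acceptors
    per donor (Kabsch–Sander bookkeeping). Same-chain pairs closer than
    |i−j| = 3 are excluded; no pattern uses them and the covalently bonded
    neighbour would otherwise score spuriously.
    """
    F = coords.shape[0]
    R = cache.n_res
    bb = cache.bb

    def pick(key):
        idx = bb[key]
        out = np.full((F, R, 3), np.nan)
        ok = idx >= 0
        out[:, ok, :] = coords[:, idx[ok], :]
        return out

    N, CA, C, O = pick("N"), pick("CA"), pick("C"), pick("O")
    H = pick("H")
    # reconstruct missing amide H from the preceding carbonyl
    need = np.isnan(H[0, :, 0]) & cache.prev_same_chain & ~cache.is_pro
    for i in np.flatnonzero(need):
        d = C[:, i - 1] - O[:, i - 1]
        H[:, i] = N[:, i] + 0.101 * d / np.linalg.norm(d, axis=1, keepdims=True)

    donor_ok = (
        cache.complete & cache.prev_same_chain & ~cache.is_pro
        & ~np.isnan(H[0, :, 0])
    )
    acc_ok = cache.complete

    def dist(a, b):
        # (F, donors, acceptors)
        return np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)

    r_on = dist(N, O)
    r_oh = dist(H, O)
    r_cn = dist(N, C)
    r_ch = dist(H, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = DSSP_Q * 0.1 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    energy = np.where(
        np.minimum.reduce([r_on, r_oh, r_cn, r_ch]) < _MIN_DIST_NM,
        np.inf,
        energy,
    )
    energy = np.nan_to_num(energy, nan=np.inf, posinf=np.inf, neginf=np.inf)
    same_chain = cache.chain_index[:, None] == cache.chain_index[None, :]
    seq_sep = np.abs(np.arange(R)[:, None] - np.arange(R)[None, :])
    invalid = (~donor_ok[:, None]) | (~acc_ok[None, :]) | (same_chain & (seq_sep < 3))
    energy[:, invalid] = np.inf

    # best-two acceptors per donor
    order = np.argsort(energy, axis=2)
    keep = np.zeros_like(energy, dtype=bool)
    fr = np.arange(F)[:, None]
    dn = np.arange(R)[None, :]
    for rank in range(min(2, R)):
        acc = order[:, :, rank]
        keep[fr, dn, acc] = True
    return keep & (energy < HBOND_ENERGY_CUTOFF)


def _assign_batch(coords: np.ndarray, cache: _BackboneCache) -> np.ndarray:
    """Five-class assignment for a frame batch; returns (F, R) int codes."""
    F = coords.shape[0]
    R = cache.n_res
    hb = _hbond_sets(coords, cache)  # [f, donor, acceptor]
    same_chain = cache.chain_index[:, None] == cache.chain_index[None, :]

    # n-turns: donor i+n → acceptor i, same chain
    turn = {}
    for n in (3, 4, 5):
        t = np.zeros((F, R), bool)
        if R > n:
            idx = np.arange(R - n)
            ok = same_chain[idx + n, idx]
            t[:, idx] = hb[:, idx + n, idx] & ok
        turn[n] = t

    helix4 = np.zeros((F, R), bool)
    helix3 = np.zeros((F, R), bool)
    for n, flags in ((4, helix4), (3, helix3)):
        t = turn[n]
        if R > n:
            start = t[:, 1:R - n + 1] & t[:, : R - n]  # turn(i−1) & turn(i)
            for off in range(n):
                flags[:, 1 + off: R - n + 1 + off] |= start

    # bridges: Hb(i,j) = CO(i) accepts from NH(j) = hb[:, j, i]
    Hb = np.transpose(hb, (0, 2, 1))

    def shift(mat, di, dj):
        out = np.zeros_like(mat)
        src_i = slice(max(0, -di), R - max(0, di))
        dst_i = slice(max(0, di), R - max(0, -di))
        src_j = slice(max(0, -dj), R - max(0, dj))
        dst_j = slice(max(0, dj), R - max(0, -dj))
        out[:, dst_i, dst_j] = mat[:, src_i, src_j]
        return out

    para = (shift(Hb, 1, 0) & np.transpose(shift(Hb, 0, -1), (0, 2, 1))) | (
        np.transpose(shift(Hb, 1, 0), (0, 2, 1)) & shift(Hb, 0, -1)
    )
    anti = (Hb & np.transpose(Hb, (0, 2, 1))) | (
        shift(Hb, 1, -1) & np.transpose(shift(Hb, 1, -1), (0, 2, 1))
    )
    seq_sep = np.abs(np.arange(R)[:, None] - np.arange(R)[None, :])
    allowed = (~same_chain) | (seq_sep >= 3)
    bridge_pair = (para | anti) & allowed
    bridge = bridge_pair.any(axis=2) | bridge_pair.any(axis=1)

    # hydrogen-bonded turn flag: interior residues of any n-turn
    turn_flag = np.zeros((F, R), bool)
    for n in (3, 4, 5):
        if R <= n:
            continue
        t = turn[n]
        for off in range(1, n):
            turn_flag[:, off: R - n + off] |= t[:, : R - n]

    # bend: Cα chain direction change > 70°
    bend = np.zeros((F, R), bool)
    ca_idx = cache.bb["CA"]
    ok = (
        (np.arange(R) >= 2) & (np.arange(R) < R - 2)
        & cache.complete
    )
    for i in np.flatnonzero(ok):
        if not (
            cache.chain_index[i - 2] == cache.chain_index[i]
            == cache.chain_index[i + 2]
        ):
            continue
        u = coords[:, ca_idx[i]] - coords[:, ca_idx[i - 2]]
        v = coords[:, ca_idx[i + 2]] - coords[:, ca_idx[i]]
        cosang = np.einsum("fj,fj->f", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        bend[:, i] = cosang < np.cos(np.deg2rad(70.0))

    out = np.full((F, R), _CODE_INDEX["C"], dtype=np.int8)
    out[turn_flag | bend] = _CODE_INDEX["T"]
    out[helix3] = _CODE_INDEX["G"]
    out[bridge] = _CODE_INDEX["E"]
    out[helix4] = _CODE_INDEX["H"]
    out[:, ~cache.complete] = _CODE_INDEX["C"]
    return out


def assign_ss(frame: np.ndarray, topology: Topology) -> list[str]:
    """Per-residue five-class labels for one frame ((n_atoms, 3) nm)."""
    cache = _BackboneCache(topology)
    if not cache.complete.all():
        warnings.warn(
            "residues with missing backbone atoms forced to COIL", stacklevel=2
        )
    codes = _assign_batch(np.asarray(frame, float)[None], cache)[0]
    return [CLASSES[c] for c in codes]


def assign_ss_ensemble(ensemble: Ensemble, batch: int = 200) -> np.ndarray:
    """Label every frame; returns (n_frames, n_residues) int8 codes.

    Codes index into :data:`CLASSES`; use :func:`labels_as_strings` for the
    compact one-char-per-residue export.
    """
    cache = _BackboneCache(ensemble.topology)
    out = np.empty((ensemble.n_frames, cache.n_res), dtype=np.int8)
    for lo in range(0, ensemble.n_frames, batch):
        out[lo: lo + batch] = _assign_batch(
            ensemble.coords[lo: lo + batch], cache
        )
    return out


def labels_as_strings(codes: np.ndarray) -> list[str]:
    return ["".join(CODES[c] for c in row) for row in np.atleast_2d(codes)]


class SSProfile:
    """Per-residue per-class mean propensity (%) with block standard errors."""

    def __init__(self, mean_pct: np.ndarray, se_pct: np.ndarray):
        self.mean_pct = np.asarray(mean_pct, float)  # (R, 5)
        self.se_pct = np.asarray(se_pct, float)
        sums = self.mean_pct.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("class fractions must sum to 100% per residue")
        if np.any(self.se_pct < 0):
            raise ValueError("standard errors must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.mean_pct.shape[0]

    def class_profile(self, label: str) -> np.ndarray:
        return self.mean_pct[:, CLASSES.index(label)]

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in range(self.n_residues):
            for k, label in enumerate(CLASSES):
                rows.append(
                    (r + 1, label, self.mean_pct[r, k], self.se_pct[r, k])
                )
        return pd.DataFrame(
            rows, columns=["residue", "class", "mean_pct", "se_pct"]
        )


def ss_propensity(
    ensemble: Ensemble,
    n_blocks: int = 4,
    labels: np.ndarray | None = None,
) -> SSProfile:
    """Ensemble propensity profile with block standard errors.

    Frames are time-sorted and must split into ``n_blocks`` equal contiguous
    blocks. Pass precomputed ``labels`` (from :func:`assign_ss_ensemble`) to
    skip re-assignment.
    """
    if ensemble.n_frames == 0:
        raise ValueError("ensemble is empty")
    if not 2 <= n_blocks <= ensemble.n_frames:
        raise ValueError("n_blocks must be in [2, n_frames]")
    rem = ensemble.n_frames % n_blocks
    if rem:
        raise ValueError(
            f"{ensemble.n_frames} frames do not split into {n_blocks} equal "
            f"blocks (remainder {rem})"
        )
    order = np.argsort(ensemble.times, kind="stable")
    if labels is None:
        labels = assign_ss_ensemble(ensemble)
    labels = labels[order]
    F, R = labels.shape
    onehot = np.eye(len(CLASSES))[labels]  # (F, R, 5)
    mean_pct = onehot.mean(axis=0) * 100.0
    block_means = onehot.reshape(n_blocks, F // n_blocks, R, len(CLASSES)).mean(
        axis=1
    ) * 100.0
    se_pct = block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return SSProfile(mean_pct, se_pct)


def ss_difference(profile_bound: SSProfile, profile_free: SSProfile) -> np.ndarray:
    """Bound-minus-free propensity difference (%), shape (R, 5)."""
    if profile_bound.n_residues != profile_free.n_residues:
        raise ValueError("profiles have different residue counts")
    return profile_bound.mean_pct - profile_free.mean_pct
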