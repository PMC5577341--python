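"""Gromos-style conformational clustering under a pairwise-RMSD cutoff.

Greedy max-neighbour clustering: the unassigned frame with the most
neighbours (pairwise Cα-RMSD strictly below the cutoff) becomes a cluster
centre, it and its neighbours are removed, and the procedure repeats. Ties
are broken by the lowest frame index, making the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble
from .geometry import kabsch_rmsd


def pairwise_rmsd_matrix(ensemble: Ensemble, selection) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs (nm) between all frame pairs."""
    sel = np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("selection must contain at least 3 atoms")
    n = ensemble.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    out = np.zeros((n, n))
    coords = ensemble.coords[:, sel]
    centred = coords - coords.mean(axis=1, keepdims=True)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(centred[i], centred[j])
    return out


@dataclass
class ClusterResult:
    """Clusters ordered by size (descending), each with a centre frame."""

    members: list  # list of int arrays
    centers: list  # centre frame index per cluster
    cutoff: float

    def __post_init__(self):
        sizes = [len(m) for m in self.members]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("clusters must be ordered by non-increasing size")
        for m, c in zip(self.members, self.centers):
            if c not in m:
                raise ValueError("cluster centre must be a member")

    @property
    def n_frames(self) -> int:
        return sum(len(m) for m in self.members)

    @property
    def sizes(self) -> list:
        return [len(m) for m in self.members]

    def to_dict(self) -> dict:
        total = self.n_frames
        return {
            "cutoff_nm": self.cutoff,
            "clusters": [
                {
                    "center": int(c),
                    "size": len(m),
                    "population_pct": 100.0 * len(m) / total,
                    "members": [int(x) for x in m],
                }
                for m, c in zip(self.members, self.centers)
            ],
        }


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Cluster a pairwise-RMSD matrix with the gromos greedy algorithm."""
    d = np.asarray(matrix, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = d.shape[0]
    neighbour = (d < cutoff) & ~np.eye(n, dtype=bool)
    unassigned = np.ones(n, bool)
    members, centers = [], []
    while unassigned.any():
        counts = (neighbour & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        cluster = np.flatnonzero(
            unassigned & (neighbour[center] | (np.arange(n) == center))
        )
        members.append(cluster)
        centers.append(center)
        unassigned[cluster] = False
    order = sorted(
        range(len(members)), key=lambda k: (-len(members[k]), centers[k])
    )
    return ClusterResult(
        [members[k] for k in order], [centers[k] for k in order], cutoff
    )


def cumulative_population(result: ClusterResult, k: int) -> float:
    """Fraction of frames covered by the k largest clusters."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if not result.members:
        raise ValueError("empty cluster result")
    sizes = result.sizes
    return min(1.0, sum(sizes[:k]) / result.n_frames)
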