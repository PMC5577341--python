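"""Free-energy landscape over the two reaction coordinates.

The 2D potential of mean force is W(bin) = −k_B·T·ln(P(bin)/P_max) over the
(nbeta, ncontact) histogram; rectangular regions of the surface define
conformational states whose populations are reported with block standard
errors, mirroring how low-free-energy basins are quantified for disordered
ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB
from .core import Ensemble


def block_standard_error(series, n_blocks: int) -> float:
    """SE of the mean from contiguous equal-length time blocks.

    The series is split into ``n_blocks`` contiguous segments (any remainder
    is truncated at the end); SE = sample sd of the block means / √n_blocks.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be at least 2")
    x = np.asarray(series, float)
    if len(x) < n_blocks:
        raise ValueError("series shorter than the number of blocks")
    m = len(x) // n_blocks
    means = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class RCSeries:
    """Per-frame reaction-coordinate values, both in [0, 1]."""

    nbeta: np.ndarray
    ncontact: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.nbeta = np.asarray(self.nbeta, float)
        self.ncontact = np.asarray(self.ncontact, float)
        if self.nbeta.shape != self.ncontact.shape:
            raise ValueError("coordinate arrays must have equal length")
        for arr, name in ((self.nbeta, "nbeta"), (self.ncontact, "ncontact")):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.times is None:
            self.times = np.arange(len(self.nbeta), dtype=float)
        else:
            self.times = np.asarray(self.times, float)

    def __len__(self) -> int:
        return len(self.nbeta)

    def time_sorted(self) -> "RCSeries":
        order = np.argsort(self.times, kind="stable")
        return RCSeries(self.nbeta[order], self.ncontact[order], self.times[order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "nbeta": self.nbeta, "ncontact": self.ncontact}
        )


@dataclass
class PMFSurface:
    """−kT ln P surface on [0,1]²; NaN marks unoccupied bins."""

    free_energy: np.ndarray  # (n_bins, n_bins), kcal/mol
    counts: np.ndarray
    edges_nbeta: np.ndarray
    edges_ncontact: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.free_energy.shape[0]):
            for j in range(self.free_energy.shape[1]):
                rows.append(
                    (
                        0.5 * (self.edges_nbeta[i] + self.edges_nbeta[i + 1]),
                        0.5 * (self.edges_ncontact[j] + self.edges_ncontact[j + 1]),
                        self.free_energy[i, j],
                        int(self.counts[i, j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["nbeta", "ncontact", "pmf_kcal_mol", "count"]
        )


def pmf2d(rc: RCSeries, n_bins: int = 20, temperature: float = 300.0) -> PMFSurface:
    """2D PMF over the reaction coordinates.

    The occupied minimum is exactly 0 (probabilities are referenced to the
    most populated bin); empty bins are NaN, never 0.
    """
    if len(rc) == 0:
        raise ValueError("reaction-coordinate series is empty")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, ex, ey = np.histogram2d(rc.nbeta, rc.ncontact, bins=[edges, edges])
    w = np.full_like(counts, np.nan)
    occ = counts > 0
    w[occ] = -KB * temperature * np.log(counts[occ] / counts.max())
    return PMFSurface(w, counts.astype(int), ex, ey, temperature)


@dataclass(frozen=True)
class StateRectangle:
    """Axis-aligned rectangle in (nbeta, ncontact) space.

    Intervals are closed on the left, open on the right, except that a right
    edge at 1.0 is closed (so the rectangles can tile [0,1]²).
    """

    name: str
    nbeta: tuple
    ncontact: tuple

    def __post_init__(self):
        for lo, hi in (self.nbeta, self.ncontact):
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"invalid interval [{lo}, {hi}) for {self.name}")

    def _axis_mask(self, x, interval):
        lo, hi = interval
        upper = x <= hi if hi >= 1.0 else x < hi
        return (x >= lo) & upper

    def contains(self, nbeta, ncontact) -> np.ndarray:
        return self._axis_mask(np.asarray(nbeta), self.nbeta) & self._axis_mask(
            np.asarray(ncontact), self.ncontact
        )

    def overlaps(self, other: "StateRectangle") -> bool:
        def ov(a, b):
            return a[0] < b[1] and b[0] < a[1]

        return ov(self.nbeta, other.nbeta) and ov(self.ncontact, other.ncontact)


#: Bundled rectangle layout used for the synthetic ensembles: boundaries sit
#: at midpoints between the discrete (nbeta, ncontact) levels the synthetic
#: state templates realise; S6 is the high-nbeta/high-ncontact hairpin corner.
DEFAULT_STATES = (
    StateRectangle("S1", (0.0, 0.11), (0.0, 0.05)),
    StateRectangle("S2", (0.0, 0.11), (0.05, 1.0)),
    StateRectangle("S3", (0.11, 0.28), (0.0, 1.0)),
    StateRectangle("S4", (0.28, 0.50), (0.0, 0.05)),
    StateRectangle("S5", (0.28, 0.50), (0.05, 1.0)),
    StateRectangle("S6", (0.50, 1.0), (0.05, 1.0)),
)


@dataclass
class StatePopulationTable:
    """Mean percentage population ± block SE per state, plus 'Others'."""

    names: list
    mean_pct: np.ndarray
    se_pct: np.ndarray

    def __post_init__(self):
        if abs(self.mean_pct.sum() - 100.0) > 1e-6:
            raise ValueError("state populations plus Others must sum to 100%")
        if np.any(self.se_pct < 0):
            raise ValueError("standard errors must be non-negative")

    def population(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.mean_pct[i]), float(self.se_pct[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state": self.names, "mean_pct": self.mean_pct, "se_pct": self.se_pct}
        )


def state_populations(
    rc: RCSeries, states=DEFAULT_STATES, n_blocks: int = 4
) -> StatePopulationTable:
    """Population of each rectangular state (on raw coordinates, not bins)."""
    states = list(states)
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"state rectangles {a.name} and {b.name} overlap")
    rc = rc.time_sorted()
    names, means, ses = [], [], []
    assigned = np.zeros(len(rc), bool)
    for s in states:
        inside = s.contains(rc.nbeta, rc.ncontact)
        assigned |= inside
        names.append(s.name)
        means.append(inside.mean() * 100.0)
        ses.append(block_standard_error(inside * 100.0, n_blocks))
    names.append("Others")
    means.append((~assigned).mean() * 100.0)
    ses.append(block_standard_error(~assigned * 100.0, n_blocks))
    return StatePopulationTable(names, np.array(means), np.array(ses))


def hairpin_subset(
    ensemble: Ensemble, rc: RCSeries, nbeta_threshold: float = 0.6
) -> Ensemble:
    """Frames with nbeta strictly above the threshold (hairpin-rich subset)."""
    if len(rc) != ensemble.n_frames:
        raise ValueError("series and ensemble lengths differ")
    return ensemble.subset(np.flatnonzero(rc.nbeta > nbeta_threshold))
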