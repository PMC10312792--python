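"""Discrepancy measures between two energy landscapes.

Four indices quantify how much two landscapes (typically estimated from two
data sets) differ:

* ``d_j`` — mean absolute difference of the pairwise couplings J over the
  N(N−1)/2 unordered ROI pairs;
* ``d_h`` — mean Hamming distance between the ±1 patterns at the (major)
  local minima, minimized over all injective matchings of the smaller set of
  minima into the larger one;
* ``d_basin`` — mean cosine distance (1 − cos angle, in [0, 2]) between the
  basin-mean activity vectors u, minimized over matchings independently of
  ``d_h``;
* ``d_l`` — normalized absolute difference of the mean branch lengths,
  |L1 − L2| / max(L1, L2) ∈ [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import perm

import numpy as np
from scipy.optimize import linear_sum_assignment

from .landscape import EnergyLandscape
from .mem import MEMParams

__all__ = [
    "Matching",
    "DiscrepancyResult",
    "d_j",
    "count_matchings",
    "d_h",
    "d_basin",
    "d_l",
    "compare_landscapes",
    "EXHAUSTIVE_LIMIT",
]

#: Largest number of injective matchings enumerated exhaustively; above this
#: the rectangular assignment problem is solved instead (identical optimum).
EXHAUSTIVE_LIMIT = 10**6


@dataclass
class Matching:
    """Injective matching of the smaller minima set into the larger.

    ``rho[ℓ]`` is the index (in the larger set) matched to minimum ℓ of the
    smaller set; ``swapped`` records whether the two landscapes were swapped
    to enforce m1 ≤ m2; ``cost`` is the minimized mean per-pair distance.
    """

    rho: tuple[int, ...]
    cost: float
    swapped: bool = False


def count_matchings(m1: int, m2: int) -> int:
    """Number of injective maps from m1 minima into m2 ≥ m1 minima."""
    if m1 > m2:
        raise ValueError("count_matchings expects m1 <= m2")
    return perm(m2, m1)


def _optimal_matching(cost: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Minimize the summed cost over injective row→column maps.

    Exhaustive enumeration (in lexicographic order, keeping the first
    optimum, hence the lexicographically smallest optimal matching) when the
    number of matchings is at most :data:`EXHAUSTIVE_LIMIT`; otherwise the
    rectangular assignment problem is solved, which attains the same cost.
    """
    m1, m2 = cost.shape
    if count_matchings(m1, m2) <= EXHAUSTIVE_LIMIT:
        best_cost = np.inf
        best_rho: tuple[int, ...] = ()
        rows = np.arange(m1)
        for rho in permutations(range(m2), m1):
            c = cost[rows, list(rho)].sum()
            if c < best_cost - 1e-12:
                best_cost, best_rho = c, rho
        return float(best_cost), best_rho
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum()), tuple(int(c) for c in cols)


def d_j(J1: np.ndarray | MEMParams, J2: np.ndarray | MEMParams) -> float:
    """Mean absolute coupling difference: (2/(N(N−1))) Σ_{i<j} |J1_ij − J2_ij|."""
    if isinstance(J1, MEMParams):
        J1 = J1.J
    if isinstance(J2, MEMParams):
        J2 = J2.J
    J1 = np.asarray(J1, dtype=float)
    J2 = np.asarray(J2, dtype=float)
    if J1.shape != J2.shape or J1.ndim != 2 or J1.shape[0] != J1.shape[1]:
        raise ValueError(f"coupling matrices must share a square shape, got {J1.shape} vs {J2.shape}")
    iu = np.triu_indices(J1.shape[0], k=1)
    return float(np.abs(J1[iu] - J2[iu]).mean())


def _matched_mean(cost: np.ndarray, swapped: bool) -> tuple[float, Matching]:
    total, rho = _optimal_matching(cost)
    value = total / cost.shape[0]
    return value, Matching(rho=rho, cost=value, swapped=swapped)


def d_h(patterns1: np.ndarray, patterns2: np.ndarray) -> tuple[float, Matching]:
    """Minimal mean Hamming distance between matched minima patterns.

    ``patterns1``/``patterns2`` are (m, N) ±1 arrays of the activity patterns
    at the (major) local minima of each landscape.  If m1 > m2 the roles are
    swapped so that the smaller set indexes the average.
    """
    p1 = np.asarray(patterns1)
    p2 = np.asarray(patterns2)
    if p1.ndim != 2 or p2.ndim != 2 or p1.shape[1] != p2.shape[1]:
        raise ValueError("pattern sets must be (m, N) with a common N")
    if p1.shape[0] == 0 or p2.shape[0] == 0:
        raise ValueError("pattern sets must be nonempty")
    swapped = p1.shape[0] > p2.shape[0]
    if swapped:
        p1, p2 = p2, p1
    cost = (p1[:, None, :] != p2[None, :, :]).sum(axis=2).astype(float)
    return _matched_mean(cost, swapped)


def d_basin(u1: np.ndarray, u2: np.ndarray) -> tuple[float, Matching]:
    """Minimal mean cosine distance between matched basin-mean vectors.

    The per-pair distance 1 − u·u′/(‖u‖‖u′‖) lies in [0, 2]; the matching is
    optimized independently of the one chosen for :func:`d_h`.
    """
    u1 = np.atleast_2d(np.asarray(u1, dtype=float))
    u2 = np.atleast_2d(np.asarray(u2, dtype=float))
    if u1.shape[1] != u2.shape[1]:
        raise ValueError("basin-mean sets must share the vector dimension")
    if u1.shape[0] == 0 or u2.shape[0] == 0:
        raise ValueError("basin-mean sets must be nonempty")
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-norm basin-mean vector (degenerate basin)")
    swapped = u1.shape[0] > u2.shape[0]
    if swapped:
        u1, u2, n1, n2 = u2, u1, n2, n1
    cost = 1.0 - (u1 @ u2.T) / np.outer(n1, n2)
    return _matched_mean(cost, swapped)


def d_l(L1: float, L2: float) -> float:
    """Normalized mean-branch-length difference |L1 − L2| / max(L1, L2).

    Defined as 0 when both landscapes have zero mean branch length (two
    single-minimum landscapes are identical under this index).
    """
    if L1 < 0 or L2 < 0:
        raise ValueError("mean branch lengths must be nonnegative")
    if L1 == 0.0 and L2 == 0.0:
        return 0.0
    return abs(L1 - L2) / max(L1, L2)


@dataclass
class DiscrepancyResult:
    """The four discrepancy indices between two landscapes."""

    dJ: float
    dH: float
    dbasin: float
    dL: float
    matching_h: Matching | None = None
    matching_basin: Matching | None = None

    def to_dict(self) -> dict:
        out = {"dJ": self.dJ, "dH": self.dH, "dbasin": self.dbasin, "dL": self.dL}
        if self.matching_h is not None:
            out["matching_h"] = {"rho": list(self.matching_h.rho), "swapped": self.matching_h.swapped}
        if self.matching_basin is not None:
            out["matching_basin"] = {
                "rho": list(self.matching_basin.rho),
                "swapped": self.matching_basin.swapped,
            }
        return out


def compare_landscapes(ls1: EnergyLandscape, ls2: EnergyLandscape) -> DiscrepancyResult:
    """Compute all four discrepancy indices between two (pruned) landscapes."""
    if ls1.n != ls2.n:
        raise ValueError("landscapes must share N")
    if ls1.params is None or ls2.params is None:
        raise ValueError("landscapes must carry their fitted parameters for dJ")
    dj = d_j(ls1.params, ls2.params)
    dh, mh = d_h(ls1.minima_patterns(), ls2.minima_patterns())
    db, mb = d_basin(ls1.basin_means(), ls2.basin_means())
    dl = d_l(ls1.mean_branch_length, ls2.mean_branch_length)
    return DiscrepancyResult(dJ=dj, dH=dh, dbasin=db, dL=dl, matching_h=mh, matching_basin=mb)
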