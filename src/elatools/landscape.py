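"""Energy-landscape structure on the 2^N hypercube of activity patterns.

A fitted pairwise maximum-entropy model induces an energy over all 2^N
binary patterns.  Two patterns are adjacent iff they differ in exactly one
entry, so the pattern space is an N-dimensional hypercube.  This module
extracts the landscape's structure:

* **local minima** — patterns with strictly lower energy than all N neighbors
  (interpreted as discrete brain states);
* **threshold energies (Eth)** — for each pair of minima, the lowest energy
  ceiling a hypercube path between them must pass (a minimax path value,
  computed by ascending-energy node insertion with union–find, equivalent to
  removing nodes in descending energy order until the pair disconnects);
* **branch lengths** — for each minimum γ, min over other minima γ′ of
  Eth(γ, γ′) − E(γ): the lowest barrier out of γ, and the length of γ's
  branch in the disconnectivity graph;
* **minor-minimum pruning** — iterative removal of minima whose branch is
  shorter than a null threshold μ′ + 2σ′ obtained from landscapes fitted to
  random fair-coin series;
* **attractive basins** — steepest-descent assignment of every pattern to a
  minimum, and the basin-mean activity vector u per minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import DisjointSet

from . import mem
from .mem import MEMParams

__all__ = [
    "EnergyLandscape",
    "BasinPartition",
    "NullBranchStats",
    "find_local_minima",
    "compute_eth",
    "branch_lengths",
    "basins",
    "null_branch_stats",
    "prune_minor_minima",
    "merge_tree",
    "merge_tree_dot",
]


def _n_from_size(size: int) -> int:
    n = int(round(np.log2(size)))
    if 2**n != size:
        raise ValueError("energy vector length must be a power of two")
    return n


def _neighbors(size: int, n: int) -> np.ndarray:
    """(2^N, N) array: entry (k, i) is state k with bit i flipped."""
    k = np.arange(size, dtype=np.int64)
    return k[:, None] ^ (1 << np.arange(n, dtype=np.int64))


def find_local_minima(energies: np.ndarray) -> np.ndarray:
    """State indices of strict local minima, sorted by (energy, index).

    A state is a local minimum iff its energy is strictly below that of all
    N Hamming-distance-1 neighbors.
    """
    e = np.asarray(energies, dtype=float)
    n = _n_from_size(e.shape[0])
    nb = _neighbors(e.shape[0], n)
    is_min = np.all(e[:, None] < e[nb], axis=1)
    idx = np.flatnonzero(is_min)
    order = np.lexsort((idx, e[idx]))
    return idx[order]


def compute_eth(energies: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Pairwise threshold energies between local minima.

    ``eth[a, b]`` is the minimax path value: the minimum over hypercube paths
    from minimum a to minimum b of the maximum energy along the path.  It is
    computed by inserting states in ascending energy order into a union–find
    structure; when two components that each contain minima first touch, the
    energy of the state being inserted is their Eth.  The diagonal is defined
    as the minima's own energies.  The result is symmetric and ultrametric.
    """
    e = np.asarray(energies, dtype=float)
    n = _n_from_size(e.shape[0])
    minima = np.asarray(minima, dtype=np.int64)
    m = len(minima)
    eth = np.zeros((m, m))
    eth[np.diag_indices(m)] = e[minima]
    if m <= 1:
        return eth
    min_rank = {int(s): i for i, s in enumerate(minima)}

    order = np.lexsort((np.arange(e.shape[0]), e))
    ds = DisjointSet([])
    members: dict[int, list[int]] = {}  # root -> minima ranks in component
    active = np.zeros(e.shape[0], dtype=bool)
    n_linked = 0
    for k in order:
        k = int(k)
        ds.add(k)
        active[k] = True
        members[k] = [min_rank[k]] if k in min_rank else []
        for i in range(n):
            nb = k ^ (1 << i)
            if not active[nb]:
                continue
            ra, rb = ds[k], ds[nb]
            if ra == rb:
                continue
            ma, mb = members.pop(ra), members.pop(rb)
            if ma and mb:
                for a in ma:
                    for b in mb:
                        eth[a, b] = eth[b, a] = e[k]
                n_linked += len(ma) * len(mb)
            ds.merge(k, nb)
            members[ds[k]] = ma + mb
        if n_linked == m * (m - 1) // 2:
            break
    return eth


def branch_lengths(energies: np.ndarray, minima: np.ndarray, eth: np.ndarray) -> np.ndarray:
    """Branch length per minimum: lowest barrier to any other minimum.

    length(γ) = min_{γ′≠γ} Eth(γ, γ′) − E(γ).  A single-minimum landscape has
    branch length 0 by convention.
    """
    e = np.asarray(energies, dtype=float)
    minima = np.asarray(minima, dtype=np.int64)
    m = len(minima)
    if m <= 1:
        return np.zeros(m)
    off = eth + np.diag(np.full(m, np.inf))
    return off.min(axis=1) - e[minima]


@dataclass
class BasinPartition:
    """Steepest-descent assignment of every state to a local minimum.

    ``assignment[k]`` is the position (in the landscape's minima list) of the
    minimum reached by the gradient-descent walk from state k; ``basin_mean``
    row ℓ is u_ℓ, the average ±1 pattern over the basin of minimum ℓ.
    """

    assignment: np.ndarray
    basin_mean: np.ndarray


def _descend_all(energies: np.ndarray) -> np.ndarray:
    """Terminal state of the steepest-descent walk from every state.

    Moves only to the strictly lowest-energy neighbor; among equally lowest
    neighbors the smallest ROI index is flipped; a state with no strictly
    lower neighbor is its own terminus.
    """
    e = np.asarray(energies, dtype=float)
    size = e.shape[0]
    n = _n_from_size(size)
    nb = _neighbors(size, n)
    nb_e = e[nb]
    best = np.argmin(nb_e, axis=1)  # argmin takes the smallest index on ties
    step = nb[np.arange(size), best]
    stay = nb_e[np.arange(size), best] >= e
    step[stay] = np.arange(size)[stay]
    # iterate the one-step map to its fixed point (path lengths <= 2^N)
    terminal = step.copy()
    while True:
        nxt = step[terminal]
        if np.array_equal(nxt, terminal):
            return terminal
        terminal = nxt


def basins(energies: np.ndarray, minima: np.ndarray) -> BasinPartition:
    """Partition all 2^N states into attractive basins of the given minima."""
    e = np.asarray(energies, dtype=float)
    minima = np.asarray(minima, dtype=np.int64)
    if len(minima) == 0:
        raise ValueError("cannot compute basins of a landscape with no local minima")
    terminal = _descend_all(e)
    rank = {int(s): i for i, s in enumerate(minima)}
    try:
        assignment = np.array([rank[int(t)] for t in terminal], dtype=np.int64)
    except KeyError as exc:  # only reachable with exactly tied energies
        raise ValueError(
            f"descent terminated at state {exc} which is not a listed minimum "
            f"(degenerate energy ties)"
        ) from None
    n = _n_from_size(e.shape[0])
    pats = mem.state_patterns(n).astype(float)
    basin_mean = np.zeros((len(minima), n))
    for i in range(len(minima)):
        basin_mean[i] = pats[assignment == i].mean(axis=0)
    return BasinPartition(assignment=assignment, basin_mean=basin_mean)


@dataclass
class EnergyLandscape:
    """Energies, minima, barriers, and branch lengths of one fitted model.

    ``minima`` holds state indices sorted by energy; ``eth`` is the matrix of
    pairwise threshold energies over those minima (diagonal = own energies);
    ``full`` points to the unpruned landscape when this instance is the
    major-minima landscape produced by :func:`prune_minor_minima`.
    """

    energies: np.ndarray
    minima: np.ndarray
    eth: np.ndarray
    branch_length: np.ndarray
    params: MEMParams | None = None
    full: "EnergyLandscape | None" = field(default=None, repr=False)

    @classmethod
    def from_params(cls, params: MEMParams) -> "EnergyLandscape":
        return cls.from_energies(mem.energies(params), params=params)

    @classmethod
    def from_energies(
        cls, energies: np.ndarray, params: MEMParams | None = None
    ) -> "EnergyLandscape":
        e = np.asarray(energies, dtype=float)
        minima = find_local_minima(e)
        eth = compute_eth(e, minima)
        bl = branch_lengths(e, minima, eth)
        return cls(energies=e, minima=minima, eth=eth, branch_length=bl, params=params)

    @property
    def n(self) -> int:
        return _n_from_size(self.energies.shape[0])

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    def minima_patterns(self) -> np.ndarray:
        """(m, N) ±1 patterns at the local minima, in minima order."""
        return mem.state_patterns(self.n)[self.minima].astype(np.int8)

    @property
    def mean_branch_length(self) -> float:
        """Average branch length over the minima (0 for a single minimum)."""
        if self.n_minima == 0:
            return 0.0
        return float(self.branch_length.mean())

    def basin_partition(self) -> BasinPartition:
        """Basins of this landscape's minima over all 2^N states.

        On a pruned landscape, states whose descent terminates in a removed
        (minor) minimum are absorbed into the surviving minimum with the
        lowest threshold energy from that minor minimum (ties broken by
        minima order).
        """
        if self.full is None:
            return basins(self.energies, self.minima)
        full = self.full
        full_part = basins(full.energies, full.minima)
        survivors = {int(s) for s in self.minima}
        # map each full-minima rank to a rank in the pruned minima list
        pruned_rank = {int(s): i for i, s in enumerate(self.minima)}
        remap = np.empty(full.n_minima, dtype=np.int64)
        for i, s in enumerate(full.minima):
            s = int(s)
            if s in survivors:
                remap[i] = pruned_rank[s]
            else:
                cols = [full.eth[i, j] for j, t in enumerate(full.minima) if int(t) in survivors]
                keep = [pruned_rank[int(t)] for t in full.minima if int(t) in survivors]
                remap[i] = keep[int(np.argmin(cols))]
        assignment = remap[full_part.assignment]
        pats = mem.state_patterns(self.n).astype(float)
        basin_mean = np.zeros((self.n_minima, self.n))
        for i in range(self.n_minima):
            basin_mean[i] = pats[assignment == i].mean(axis=0)
        return BasinPartition(assignment=assignment, basin_mean=basin_mean)

    def basin_means(self) -> np.ndarray:
        """(m, N) basin-mean activity vectors u, in minima order."""
        return self.basin_partition().basin_mean


@dataclass
class NullBranchStats:
    """Mean and sd of the maximum branch length under fair-coin null series."""

    mu_prime: float
    sigma_prime: float
    n_reps: int
    series_length: int

    @property
    def threshold(self) -> float:
        """Pruning threshold μ′ + 2σ′."""
        return self.mu_prime + 2.0 * self.sigma_prime


def null_branch_stats(
    n_rois: int,
    t_max: int,
    n_reps: int = 100,
    length_multiplier: int = 4,
    seed: int | np.random.SeedSequence = 0,
    eps: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> NullBranchStats:
    """Null distribution of the maximum branch length from random series.

    Each replicate draws an N × (multiplier·tmax) fair-coin ±1 series, fits
    the pairwise model by likelihood maximization, builds the landscape, and
    records the maximum branch length.  Minima of such landscapes carry no
    signal, so μ′ + 2σ′ serves as the significance threshold below which a
    branch is deemed minor.  Replicates whose fit fails to converge are
    excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    length = length_multiplier * t_max
    maxima = []
    n_failed = 0
    for _ in range(n_reps):
        v = rng.integers(0, 2, size=(n_rois, length)) * 2 - 1
        fit = mem.fit_likelihood_max(
            mem.empirical_moments(v), eps=eps, tol=tol, max_iter=max_iter
        )
        if not fit.converged:
            n_failed += 1
            continue
        ls = EnergyLandscape.from_params(fit.params)
        maxima.append(ls.branch_length.max() if ls.n_minima else 0.0)
    if n_failed:
        warnings.warn(
            f"{n_failed}/{n_reps} null replicates excluded (fit did not converge)",
            RuntimeWarning,
            stacklevel=2,
        )
    maxima = np.asarray(maxima)
    return NullBranchStats(
        mu_prime=float(maxima.mean()),
        sigma_prime=float(maxima.std()),
        n_reps=len(maxima),
        series_length=length,
    )


def prune_minor_minima(
    landscape: EnergyLandscape, stats: NullBranchStats | float
) -> EnergyLandscape:
    """Iteratively remove minima whose branch is shorter than the threshold.

    At each step the branch lengths of the surviving minima are recomputed
    over the threshold-energy matrix restricted to survivors; the minimum
    with the shortest branch is removed if that branch is below the
    threshold μ′ + 2σ′.  The global minimum is never removed (if it owns the
    shortest branch the next-shortest candidate is considered), so at least
    one minimum always survives.
    """
    threshold = stats.threshold if isinstance(stats, NullBranchStats) else float(stats)
    base = landscape.full if landscape.full is not None else landscape
    e = base.energies
    keep = list(range(base.n_minima))
    # base.minima is sorted by energy, so position 0 is the global minimum
    while len(keep) > 1:
        sub_eth = base.eth[np.ix_(keep, keep)]
        bl = branch_lengths(e, base.minima[keep], sub_eth)
        order = np.argsort(bl, kind="stable")
        removed = False
        for pos in order:
            if keep[pos] == 0:
                continue  # protect the global minimum
            if bl[pos] < threshold:
                del keep[pos]
                removed = True
            break
        if not removed:
            break
    minima = base.minima[keep]
    eth = base.eth[np.ix_(keep, keep)]
    bl = branch_lengths(e, minima, eth)
    return EnergyLandscape(
        energies=e, minima=minima, eth=eth, branch_length=bl, params=base.params, full=base
    )


# ---------------------------------------------------------------------------
# disconnectivity-graph export


def merge_tree(landscape: EnergyLandscape) -> dict:
    """Disconnectivity graph as a nested merge tree (JSON-serializable).

    Leaves are local minima (state index, ±1 pattern string, energy);
    internal nodes are merge events at increasing threshold energies.
    """
    pats = landscape.minima_patterns()

    def leaf(i: int) -> dict:
        return {
            "type": "minimum",
            "state": int(landscape.minima[i]),
            "pattern": "".join("+" if s > 0 else "-" for s in pats[i]),
            "energy": float(landscape.energies[landscape.minima[i]]),
        }

    m = landscape.n_minima
    if m == 0:
        return {"type": "empty"}
    clusters: list[tuple[set[int], dict]] = [({i}, leaf(i)) for i in range(m)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                v = min(
                    landscape.eth[i, j] for i in clusters[a][0] for j in clusters[b][0]
                )
                if best is None or v < best[0]:
                    best = (v, a, b)
        v, a, b = best
        sa, na = clusters[a]
        sb, nb = clusters[b]
        merged = ({*sa, *sb}, {"type": "merge", "eth": float(v), "children": [na, nb]})
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return clusters[0][1]


def merge_tree_dot(landscape: EnergyLandscape) -> str:
    """DOT rendering of the merge tree, for quick visual inspection."""
    tree = merge_tree(landscape)
    lines = ["digraph disconnectivity {", "  node [shape=box];"]
    counter = [0]

    def walk(node: dict) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if node["type"] == "minimum":
            lines.append(f'  {name} [label="{node["pattern"]}\\nE={node["energy"]:.4g}"];')
        else:
            lines.append(f'  {name} [label="Eth={node["eth"]:.4g}", shape=ellipse];')
            for child in node["children"]:
                lines.append(f"  {name} -> {walk(child)};")
        return name

    if tree.get("type") != "empty":
        walk(tree)
    lines.append("}")
    return "\n".join(lines)
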