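"""Local minima, threshold energies, branch lengths, pruning, and basins."""

import numpy as np
import pytest

from elatools import (
    EnergyLandscape,
    MEMParams,
    NullBranchStats,
    null_branch_stats,
    prune_minor_minima,
)
from elatools.landscape import (
    basins,
    branch_lengths,
    compute_eth,
    find_local_minima,
    merge_tree,
    merge_tree_dot,
)
from elatools.mem import energies, state_patterns


def _brute_minima(e: np.ndarray) -> np.ndarray:
    """Direct definition scan: strictly lower than every 1-flip neighbor."""
    n = int(np.log2(len(e)))
    out = []
    for k in range(len(e)):
        if all(e[k] < e[k ^ (1 << i)] for i in range(n)):
            out.append(k)
    out = np.array(out, dtype=np.int64)
    return out[np.lexsort((out, e[out]))]


def _brute_eth(e: np.ndarray, a: int, b: int) -> float:
    """Minimax path value by the connectivity-threshold definition.

    The pair's Eth is the smallest energy ceiling E such that a and b are
    connected in the subgraph of states with energy <= E (equivalently, the
    energy of the last node removed in descending-energy removal).
    """
    n = int(np.log2(len(e)))
    for ceil in sorted(e):
        allowed = e <= ceil
        if not (allowed[a] and allowed[b]):
            continue
        seen = {a}
        stack = [a]
        while stack:
            k = stack.pop()
            for i in range(n):
                nb = k ^ (1 << i)
                if allowed[nb] and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if b in seen:
            return float(ceil)
    raise AssertionError("hypercube is connected; unreachable")


class TestFindLocalMinima:
    def test_monotone_field_single_minimum(self):
        p = MEMParams(h=np.ones(3), J=np.zeros((3, 3)))
        minima = find_local_minima(energies(p))
        assert list(minima) == [7]  # all-(+1) state

    def test_ferromagnet_two_minima(self, ferro2):
        assert list(find_local_minima(energies(ferro2))) == [0, 3]

    def test_matches_brute_force_on_random_landscapes(self, rng):
        for _ in range(100):
            e = rng.normal(size=32)
            assert np.array_equal(find_local_minima(e), _brute_minima(e))

    def test_sorted_by_energy(self, rng):
        e = rng.normal(size=16)
        minima = find_local_minima(e)
        assert np.all(np.diff(e[minima]) >= 0)


class TestComputeEth:
    def test_two_spin_barrier(self):
        p = MEMParams(h=[0, 0], J=[[0, 1], [1, 0]])
        e = energies(p)
        minima = find_local_minima(e)
        eth = compute_eth(e, minima)
        assert eth[0, 1] == pytest.approx(1.0)
        # barrier from the viewpoint of either minimum: Eth − E = 1 − (−1) = 2
        assert eth[0, 1] - e[minima[0]] == pytest.approx(2.0)

    def test_diagonal_is_own_energy(self, rng):
        e = rng.normal(size=16)
        minima = find_local_minima(e)
        eth = compute_eth(e, minima)
        assert np.allclose(np.diag(eth), e[minima])

    def test_matches_brute_force_minimax(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 5))
            e = rng.normal(size=2**n)
            minima = find_local_minima(e)
            eth = compute_eth(e, minima)
            for a in range(len(minima)):
                for b in range(a + 1, len(minima)):
                    assert eth[a, b] == pytest.approx(
                        _brute_eth(e, int(minima[a]), int(minima[b]))
                    )

    def test_ultrametric_and_symmetric(self, rng):
        for _ in range(20):
            e = rng.normal(size=32)
            minima = find_local_minima(e)
            eth = compute_eth(e, minima)
            assert np.allclose(eth, eth.T)
            m = len(minima)
            for a in range(m):
                for b in range(m):
                    for c in range(m):
                        assert eth[a, c] <= max(eth[a, b], eth[b, c]) + 1e-12
            # eth dominates both endpoint energies
            for a in range(m):
                for b in range(m):
                    assert eth[a, b] >= max(e[minima[a]], e[minima[b]]) - 1e-12


class TestBranchLengths:
    def test_single_minimum_zero(self):
        p = MEMParams(h=np.ones(3), J=np.zeros((3, 3)))
        ls = EnergyLandscape.from_params(p)
        assert ls.n_minima == 1
        assert ls.branch_length[0] == 0.0
        assert ls.mean_branch_length == 0.0

    def test_ferromagnet_both_two(self):
        p = MEMParams(h=[0, 0], J=[[0, 1], [1, 0]])
        ls = EnergyLandscape.from_params(p)
        assert np.allclose(ls.branch_length, [2.0, 2.0])

    def test_nonnegative(self, rng):
        for _ in range(20):
            e = rng.normal(size=64)
            minima = find_local_minima(e)
            bl = branch_lengths(e, minima, compute_eth(e, minima))
            assert np.all(bl >= -1e-12)


class TestNullBranchStats:
    def test_reproducible_and_positive(self):
        s1 = null_branch_stats(5, 200, n_reps=10, seed=4)
        s2 = null_branch_stats(5, 200, n_reps=10, seed=4)
        assert s1.mu_prime == s2.mu_prime and s1.sigma_prime == s2.sigma_prime
        assert s1.mu_prime > 0  # random landscapes generically have >1 minimum
        assert s1.series_length == 800
        assert s1.threshold == pytest.approx(s1.mu_prime + 2 * s1.sigma_prime)

    def test_mean_stable_under_more_reps(self):
        s1 = null_branch_stats(5, 100, n_reps=12, seed=4)
        s2 = null_branch_stats(5, 100, n_reps=24, seed=4)
        se = s1.sigma_prime / np.sqrt(s1.n_reps)
        assert abs(s1.mu_prime - s2.mu_prime) <= 4 * se


class TestPruneMinorMinima:
    def _landscape(self, seed=0):
        r = np.random.default_rng(seed)
        J = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        J[iu] = r.normal(0, 0.6, size=len(iu[0]))
        return EnergyLandscape.from_params(MEMParams(h=r.normal(0, 0.1, 5), J=J + J.T))

    def test_zero_threshold_keeps_all(self):
        ls = self._landscape(3)
        pruned = prune_minor_minima(ls, 0.0)
        assert np.array_equal(pruned.minima, ls.minima)

    def test_huge_threshold_keeps_only_global_minimum(self):
        ls = self._landscape(3)
        assert ls.n_minima > 1
        pruned = prune_minor_minima(ls, 1e9)
        assert pruned.n_minima == 1
        assert pruned.minima[0] == ls.minima[0]  # the global minimum survives

    def test_idempotent(self):
        ls = self._landscape(5)
        stats = NullBranchStats(mu_prime=0.1, sigma_prime=0.05, n_reps=100, series_length=800)
        once = prune_minor_minima(ls, stats)
        twice = prune_minor_minima(once, stats)
        assert np.array_equal(once.minima, twice.minima)
        assert np.allclose(once.branch_length, twice.branch_length)

    def test_survivor_branches_meet_threshold(self):
        ls = self._landscape(7)
        thr = 0.3
        pruned = prune_minor_minima(ls, thr)
        if pruned.n_minima > 1:
            assert np.all(pruned.branch_length >= thr)


class TestBasins:
    def test_minimum_assigned_to_itself(self, rng):
        e = rng.normal(size=32)
        minima = find_local_minima(e)
        part = basins(e, minima)
        for i, s in enumerate(minima):
            assert part.assignment[s] == i

    def test_ferromagnet_partition_and_means(self, ferro2):
        e = energies(ferro2)
        part = basins(e, find_local_minima(e))
        # tie rule: flip the smallest ROI index, so (+,−)→(−,−), (−,+)→(+,+)
        assert list(part.assignment) == [0, 0, 1, 1]
        assert np.allclose(part.basin_mean[0], [0.0, -1.0])
        assert np.allclose(part.basin_mean[1], [0.0, 1.0])

    def test_all_states_partitioned(self, rng):
        e = rng.normal(size=64)
        minima = find_local_minima(e)
        part = basins(e, minima)
        assert part.assignment.shape == (64,)
        assert set(np.unique(part.assignment)) == set(range(len(minima)))

    def test_singleton_basin_mean_is_pattern(self):
        p = MEMParams(h=np.ones(3) * 2, J=np.zeros((3, 3)))
        ls = EnergyLandscape.from_params(p)
        u = ls.basin_means()
        # single minimum at all-(+1); its basin covers everything, but the
        # minimum's own pattern is all ones
        assert np.array_equal(ls.minima_patterns()[0], np.ones(3, dtype=np.int8))

    def test_pruned_basins_absorbed_into_nearest_major(self):
        r = np.random.default_rng(11)
        J = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        J[iu] = r.normal(0, 0.7, size=len(iu[0]))
        ls = EnergyLandscape.from_params(MEMParams(h=np.zeros(5), J=J + J.T))
        pruned = prune_minor_minima(ls, np.median(ls.branch_length))
        part = pruned.basin_partition()
        assert part.assignment.shape == (32,)
        assert set(np.unique(part.assignment)) <= set(range(pruned.n_minima))
        # every state still assigned; means have unit-bounded entries
        assert np.all(np.abs(part.basin_mean) <= 1.0 + 1e-12)


class TestMergeTree:
    def test_two_minima_tree(self, ferro2):
        ls = EnergyLandscape.from_params(MEMParams(h=[0, 0], J=[[0, 1], [1, 0]]))
        tree = merge_tree(ls)
        assert tree["type"] == "merge"
        assert tree["eth"] == pytest.approx(1.0)
        kinds = {c["type"] for c in tree["children"]}
        assert kinds == {"minimum"}

    def test_dot_renders(self):
        ls = EnergyLandscape.from_params(MEMParams(h=[0, 0], J=[[0, 1], [1, 0]]))
        dot = merge_tree_dot(ls)
        assert dot.startswith("digraph") and "Eth" in dot
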