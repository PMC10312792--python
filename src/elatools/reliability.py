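"""Within- vs between-participant landscape consistency and the ND test.

Given a complete participants × sessions table of binarized series, the
test-retest question is whether landscapes estimated from different sessions
of the *same* participant agree better than landscapes from *different*
participants.  Two designs are supported:

* **concatenated** — each landscape is estimated from data concatenated over
  m sessions (likelihood maximization needs the extra data).  d1 averages
  discrepancies between two disjoint random m-session concatenations of the
  same participant (``reps_within`` draws per participant); d2 averages
  discrepancies between concatenations of one session over two random halves
  of the participants (``reps_between`` draws per session).
* **pairwise** — each landscape is estimated from a single session (e.g. with
  the variational-Bayes estimator).  d1 averages the discrepancy over all
  within-participant session pairs; d2 over all same-session participant
  pairs.

The statistic is ND = d2/d1 ("normalized distance"); ND > 1 indicates
participant-specific (fingerprint-like) landscapes.  Its significance is
assessed by a permutation test: cells of the table are reshuffled (globally,
or participants permuted within each session column), ND is recomputed
identically, and the p-value is the fraction of permutations whose ND
exceeds the observed one.  Under exchangeability the null ND distribution is
centered near 1.

Estimation of a landscape from a given data set is deterministic, so
estimates are memoized by cell identity (and, for concatenation, by the
unordered set of concatenated cells — the fitted model depends on the data
only through time-averaged moments).  Permutation replicates therefore reuse
estimates, with results identical to naive re-running.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import mem
from .bayes import vb_fit
from .discrepancy import d_basin, d_h, d_j, d_l
from .landscape import EnergyLandscape, NullBranchStats, null_branch_stats, prune_minor_minima
from .series import BinaryTimeSeries

__all__ = [
    "SessionTable",
    "PermutationResult",
    "concat_sessions",
    "d1_d2_pairwise",
    "d1_d2_concatenated",
    "permutation_test",
    "MEASURES",
]

MEASURES = ("dJ", "dH", "dbasin", "dL")
_LANDSCAPE_MEASURES = {"dH", "dbasin", "dL"}


@dataclass
class SessionTable:
    """Complete participants × sessions grid of time series."""

    grid: dict
    participants: list[str]
    sessions: list[str]

    def __post_init__(self) -> None:
        missing = [
            (p, s) for p in self.participants for s in self.sessions if (p, s) not in self.grid
        ]
        if missing:
            raise ValueError(f"incomplete session table; missing cell {missing[0]}")
        ns = {self.grid[(p, s)].n for p in self.participants for s in self.sessions}
        if len(ns) != 1:
            raise ValueError(f"all cells must share N; found {sorted(ns)}")

    @property
    def n(self) -> int:
        return self.grid[(self.participants[0], self.sessions[0])].n

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def cell(self, participant: str, session: str):
        return self.grid[(participant, session)]


@dataclass
class PermutationResult:
    """Observed ND, its permutation-null distribution, and the p-value."""

    nd_observed: float
    nd_null: np.ndarray
    p_value: float
    d1_observed: float
    d2_observed: float
    design: str
    shuffle: str
    measure: str
    estimator: str
    seed: int | None
    c: int
    n_excluded: int = 0

    def p_text(self) -> str:
        """Human-readable p-value; a zero count is reported as a bound."""
        if self.p_value == 0.0 and self.c > 0:
            return f"p < {1.0 / self.c:g}"
        return f"p = {self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "nd_observed": self.nd_observed,
            "nd_null": [float(x) for x in self.nd_null],
            "p_value": self.p_value,
            "p_text": self.p_text(),
            "d1_observed": self.d1_observed,
            "d2_observed": self.d2_observed,
            "design": self.design,
            "shuffle": self.shuffle,
            "measure": self.measure,
            "estimator": self.estimator,
            "seed": self.seed,
            "c": self.c,
            "n_excluded": self.n_excluded,
        }


def concat_sessions(
    table: SessionTable, participant: str, session_ids: Iterable[str]
) -> BinaryTimeSeries:
    """Column-wise concatenation of a participant's sessions, in given order."""
    session_ids = list(session_ids)
    if not session_ids:
        raise ValueError("need at least one session id")
    parts = []
    for s in session_ids:
        if (participant, s) not in table.grid:
            raise KeyError(f"missing cell ({participant!r}, {s!r})")
        parts.append(table.grid[(participant, s)].values)
    cell0 = table.grid[(participant, session_ids[0])]
    return BinaryTimeSeries(
        values=np.concatenate(parts, axis=1),
        roi_labels=list(cell0.roi_labels),
        meta={"participant_id": participant, "session_ids": list(session_ids)},
    )


# ---------------------------------------------------------------------------
# estimation cache


@dataclass
class _Artifact:
    """Fitted parameters and (optionally) the pruned landscape of one data set."""

    params: mem.MEMParams
    landscape: EnergyLandscape | None = None
    minima_patterns: np.ndarray | None = None
    basin_means: np.ndarray | None = None
    mean_branch_length: float | None = None


class _Estimator:
    """Memoized estimation of per-cell / per-concatenation artifacts."""

    def __init__(
        self,
        table: SessionTable,
        estimator: str,
        needs_landscape: bool,
        seed_seq: np.random.SeedSequence,
        eps: float = 0.2,
        tol: float = 1e-6,
        max_iter: int = 500_000,
        null_reps: int = 100,
    ):
        if estimator not in ("mle", "vb"):
            raise ValueError(f"unknown estimator {estimator!r}")
        self.table = table
        self.estimator = estimator
        self.needs_landscape = needs_landscape
        self.eps, self.tol, self.max_iter = eps, tol, max_iter
        self.null_reps = null_reps
        self.cells = [(p, s) for p in table.participants for s in table.sessions]
        self.arrays = [table.grid[c].values for c in self.cells]
        vb_seq, null_seq = seed_seq.spawn(2)
        self._null_seq = null_seq
        self._null_stats: dict[tuple[int, int], NullBranchStats] = {}
        self._cell_art: dict[int, _Artifact] = {}
        self._concat_art: dict[tuple[int, ...], _Artifact] = {}
        self._vb_params: list[mem.MEMParams] | None = None
        self._vb_seed = vb_seq

    # -- null branch statistics, cached per (N, estimation length) ----------
    def null_stats(self, length: int) -> NullBranchStats:
        key = (self.table.n, length)
        if key not in self._null_stats:
            child = np.random.SeedSequence(
                entropy=self._null_seq.entropy, spawn_key=(*self._null_seq.spawn_key, length)
            )
            self._null_stats[key] = null_branch_stats(
                self.table.n,
                length,
                n_reps=self.null_reps,
                length_multiplier=1,  # `length` is already the estimation length
                seed=child,
                eps=self.eps,
                tol=self.tol,
                max_iter=self.max_iter,
            )
        return self._null_stats[key]

    def _finalize(self, params: mem.MEMParams, length: int) -> _Artifact:
        art = _Artifact(params=params)
        if self.needs_landscape:
            ls = prune_minor_minima(EnergyLandscape.from_params(params), self.null_stats(length))
            art.landscape = ls
            art.minima_patterns = ls.minima_patterns()
            art.basin_means = ls.basin_means()
            art.mean_branch_length = ls.mean_branch_length
        return art

    def _fit_mle(self, values: np.ndarray) -> mem.MEMParams:
        fit = mem.fit_likelihood_max(
            mem.empirical_moments(values), eps=self.eps, tol=self.tol, max_iter=self.max_iter
        )
        if not fit.converged:
            raise RuntimeError(
                f"likelihood maximization did not converge "
                f"(final moment error {fit.final_moment_error:.3g})"
            )
        return fit.params

    def cell_artifact(self, cell_id: int) -> _Artifact:
        """Single-session artifact (pairwise design)."""
        if cell_id not in self._cell_art:
            if self.estimator == "vb":
                if self._vb_params is None:
                    _, post = vb_fit(self.arrays, seed=self._vb_seed)
                    self._vb_params = post.session_params(self.table.n)
                params = self._vb_params[cell_id]
            else:
                params = self._fit_mle(self.arrays[cell_id])
            self._cell_art[cell_id] = self._finalize(params, self.arrays[cell_id].shape[1])
        return self._cell_art[cell_id]

    def concat_artifact(self, cell_ids: tuple[int, ...]) -> _Artifact:
        """Artifact of data concatenated over several cells (concatenated design)."""
        key = tuple(sorted(cell_ids))
        if key not in self._concat_art:
            values = np.concatenate([self.arrays[i] for i in key], axis=1)
            params = self._fit_mle(values)
            self._concat_art[key] = self._finalize(params, values.shape[1])
        return self._concat_art[key]

    def measure_between(self, a: _Artifact, b: _Artifact, measure: str) -> float:
        if measure == "dJ":
            return d_j(a.params, b.params)
        if measure == "dH":
            return d_h(a.minima_patterns, b.minima_patterns)[0]
        if measure == "dbasin":
            return d_basin(a.basin_means, b.basin_means)[0]
        if measure == "dL":
            return d_l(a.mean_branch_length, b.mean_branch_length)
        raise ValueError(f"unknown measure {measure!r}")


def _check_measure(measure: str) -> bool:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    return measure in _LANDSCAPE_MEASURES


def _grid_observed(table: SessionTable) -> np.ndarray:
    return np.arange(table.n_participants * table.n_sessions).reshape(
        table.n_participants, table.n_sessions
    )


# ---------------------------------------------------------------------------
# pairwise design


def _d1_d2_pairwise_from_grid(
    est: _Estimator, grid: np.ndarray, measure: str
) -> tuple[float, float, dict]:
    n_p, n_s = grid.shape
    within = []
    for p in range(n_p):
        for s1 in range(n_s):
            for s2 in range(s1 + 1, n_s):
                within.append(
                    est.measure_between(
                        est.cell_artifact(int(grid[p, s1])),
                        est.cell_artifact(int(grid[p, s2])),
                        measure,
                    )
                )
    between = []
    for s in range(n_s):
        for p1 in range(n_p):
            for p2 in range(p1 + 1, n_p):
                between.append(
                    est.measure_between(
                        est.cell_artifact(int(grid[p1, s])),
                        est.cell_artifact(int(grid[p2, s])),
                        measure,
                    )
                )
    samples = {"within": np.asarray(within), "between": np.asarray(between)}
    return float(np.mean(within)), float(np.mean(between)), samples


def d1_d2_pairwise(
    table: SessionTable,
    measure: str = "dJ",
    estimator: str = "mle",
    seed: int = 0,
    **est_kwargs,
) -> tuple[float, float, dict]:
    """Within-/between-participant mean discrepancy from single-session fits.

    d1 averages the measure over all P·S(S−1)/2 within-participant session
    pairs, d2 over all S·P(P−1)/2 same-session participant pairs.
    """
    if table.n_sessions < 2 or table.n_participants < 2:
        raise ValueError("pairwise design needs >= 2 sessions and >= 2 participants")
    needs = _check_measure(measure)
    est = _Estimator(table, estimator, needs, np.random.SeedSequence(seed), **est_kwargs)
    return _d1_d2_pairwise_from_grid(est, _grid_observed(table), measure)


# ---------------------------------------------------------------------------
# concatenated design


def _d1_d2_concatenated_from_grid(
    est: _Estimator,
    grid: np.ndarray,
    measure: str,
    m: int,
    reps_within: int,
    reps_between: int,
    rng: np.random.Generator,
) -> tuple[float, float, dict]:
    n_p, n_s = grid.shape
    within = []
    for p in range(n_p):
        for _ in range(reps_within):
            pick = rng.choice(n_s, size=2 * m, replace=False)
            a = est.concat_artifact(tuple(int(grid[p, s]) for s in pick[:m]))
            b = est.concat_artifact(tuple(int(grid[p, s]) for s in pick[m:]))
            within.append(est.measure_between(a, b, measure))
    half = n_p // 2
    between = []
    for s in range(n_s):
        for _ in range(reps_between):
            order = rng.permutation(n_p)
            a = est.concat_artifact(tuple(int(grid[p, s]) for p in order[:half]))
            b = est.concat_artifact(tuple(int(grid[p, s]) for p in order[half : 2 * half]))
            between.append(est.measure_between(a, b, measure))
    samples = {"within": np.asarray(within), "between": np.asarray(between)}
    return float(np.mean(within)), float(np.mean(between)), samples


def d1_d2_concatenated(
    table: SessionTable,
    m: int = 4,
    reps_within: int = 10,
    reps_between: int = 10,
    measure: str = "dJ",
    estimator: str = "mle",
    seed: int = 0,
    **est_kwargs,
) -> tuple[float, float, dict]:
    """Within-/between-participant mean discrepancy from m-session concatenations.

    Per participant, ``reps_within`` random draws of two disjoint m-session
    sets feed d1; per session, ``reps_between`` random half/half participant
    splits feed d2.
    """
    if estimator != "mle":
        raise ValueError("the concatenated design uses the likelihood-maximization estimator")
    if table.n_sessions < 2 * m:
        raise ValueError(
            f"need >= {2 * m} sessions for two disjoint sets of {m}, have {table.n_sessions}"
        )
    if table.n_participants < 2:
        raise ValueError("need >= 2 participants")
    needs = _check_measure(measure)
    seq = np.random.SeedSequence(seed)
    est_seq, draw_seq = seq.spawn(2)
    est = _Estimator(table, estimator, needs, est_seq, **est_kwargs)
    rng = np.random.default_rng(draw_seq)
    return _d1_d2_concatenated_from_grid(
        est, _grid_observed(table), measure, m, reps_within, reps_between, rng
    )


# ---------------------------------------------------------------------------
# permutation test


def _permute_grid(grid: np.ndarray, shuffle: str, rng: np.random.Generator) -> np.ndarray:
    if shuffle == "global":
        flat = rng.permutation(grid.size)
        return flat.reshape(grid.shape)
    if shuffle == "within_session":
        out = grid.copy()
        for s in range(grid.shape[1]):
            out[:, s] = out[rng.permutation(grid.shape[0]), s]
        return out
    raise ValueError(f"unknown shuffle {shuffle!r}")


def permutation_test(
    table: SessionTable,
    design: str = "pairwise",
    measure: str = "dJ",
    estimator: str = "mle",
    c: int = 1000,
    shuffle: str = "global",
    seed: int = 0,
    m: int = 4,
    reps_within: int = 10,
    reps_between: int = 10,
    **est_kwargs,
) -> PermutationResult:
    """Permutation test of ND = d2/d1 against cell-exchangeability.

    The observed ND comes from the unshuffled table; each of ``c`` replicates
    reassigns cells (globally without replacement, or permuting participants
    within each session column) and recomputes ND identically.  The p-value
    is the fraction of replicates with ND *strictly larger* than observed.
    Replicates with d1 = 0 (degenerate) are excluded and counted.
    """
    if design not in ("pairwise", "concatenated"):
        raise ValueError(f"unknown design {design!r}")
    needs = _check_measure(measure)
    seq = np.random.SeedSequence(seed)
    est_seq, perm_seq, draw_seq = seq.spawn(3)
    est = _Estimator(table, estimator, needs, est_seq, **est_kwargs)
    grid0 = _grid_observed(table)

    def nd_of(grid: np.ndarray, rng: np.random.Generator) -> tuple[float, float, float]:
        if design == "pairwise":
            d1, d2, _ = _d1_d2_pairwise_from_grid(est, grid, measure)
        else:
            d1, d2, _ = _d1_d2_concatenated_from_grid(
                est, grid, measure, m, reps_within, reps_between, rng
            )
        return d1, d2, (d2 / d1 if d1 > 0 else float("nan"))

    draw_rng = np.random.default_rng(draw_seq)
    d1_obs, d2_obs, nd_obs = nd_of(grid0, draw_rng)
    if not np.isfinite(nd_obs):
        raise ValueError("observed d1 = 0; ND undefined for this table")

    perm_rng = np.random.default_rng(perm_seq)
    nd_null = []
    n_excluded = 0
    for _ in range(c):
        grid = _permute_grid(grid0, shuffle, perm_rng)
        _, _, nd = nd_of(grid, perm_rng)
        if np.isfinite(nd):
            nd_null.append(nd)
        else:
            n_excluded += 1
    nd_null = np.asarray(nd_null)
    c_eff = len(nd_null)
    p = float(np.sum(nd_null > nd_obs) / c_eff) if c_eff else float("nan")
    return PermutationResult(
        nd_observed=float(nd_obs),
        nd_null=nd_null,
        p_value=p,
        d1_observed=float(d1_obs),
        d2_observed=float(d2_obs),
        design=design,
        shuffle=shuffle,
        measure=measure,
        estimator=estimator,
        seed=seed,
        c=c_eff,
        n_excluded=n_excluded,
    )
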