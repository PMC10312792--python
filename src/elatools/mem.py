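"""Exact pairwise maximum-entropy (Ising) model over ±1 activity patterns.

The model assigns each activity pattern ``V = (σ_1, …, σ_N)``, σ_i ∈ {−1, +1},
an energy

    E(V) = −Σ_i h_i σ_i − (1/2) Σ_i Σ_j J_ij σ_i σ_j

with symmetric couplings J (zero diagonal) and biases h, and the Boltzmann
probability ``P(V) ∝ exp(−E(V))``.  Everything here works by exact enumeration
of the 2^N patterns, which restricts N to small systems (the intended regime,
e.g. brain networks with N ≤ 15 regions).

State encoding is little-endian: state index ``k`` has bit ``i`` (least
significant bit = ROI 0) equal to 1 for σ_i = +1 and 0 for σ_i = −1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "MEMParams",
    "Moments",
    "PatternDistribution",
    "FitResult",
    "state_patterns",
    "energy",
    "energies",
    "pattern_probabilities",
    "empirical_moments",
    "empirical_distribution",
    "moments_from_distribution",
    "model_moments",
    "fit_likelihood_max",
    "fit_independent",
    "accuracy_rd",
    "MAX_ENUM_N",
]

#: Largest system size for which 2^N states are enumerated exactly.
MAX_ENUM_N = 15


def _check_enum(n: int) -> None:
    if n > MAX_ENUM_N:
        raise ValueError(
            f"N={n} exceeds the exact-enumeration limit N<={MAX_ENUM_N} "
            f"(2^N states are enumerated explicitly)"
        )


@lru_cache(maxsize=32)
def _state_patterns_cached(n: int) -> np.ndarray:
    k = np.arange(2**n, dtype=np.int64)
    bits = (k[:, None] >> np.arange(n)) & 1
    pats = 2 * bits - 1
    pats.setflags(write=False)
    return pats.astype(np.int8)


def state_patterns(n: int) -> np.ndarray:
    """Return the (2^N, N) matrix of ±1 patterns in canonical state order.

    Row ``k`` is the pattern whose i-th entry is +1 iff bit ``i`` of ``k``
    is set (little-endian encoding).  The array is read-only and cached.
    """
    _check_enum(n)
    return _state_patterns_cached(n)


@dataclass
class MEMParams:
    """Parameters (h, J) of the pairwise maximum-entropy model.

    ``h`` is the length-N bias vector; ``J`` the symmetric N×N coupling
    matrix with zero diagonal.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.ndim != 1:
            raise ValueError("h must be a vector")
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError(f"J must be {n}x{n}, got {self.J.shape}")
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-10):
            raise ValueError("J must have zero diagonal")
        # canonicalize exactly
        self.J = (self.J + self.J.T) / 2.0
        np.fill_diagonal(self.J, 0.0)

    @property
    def n(self) -> int:
        return self.h.shape[0]

    @property
    def m(self) -> int:
        """Number of free parameters, M = N(N+1)/2."""
        return self.n * (self.n + 1) // 2

    def flatten(self) -> np.ndarray:
        """Canonical M-vector (h_1..h_N, J_12, J_13, …, J_{N−1,N})."""
        iu = np.triu_indices(self.n, k=1)
        return np.concatenate([self.h, self.J[iu]])

    @classmethod
    def from_flat(cls, theta: np.ndarray, n: int) -> "MEMParams":
        theta = np.asarray(theta, dtype=float)
        m = n * (n + 1) // 2
        if theta.shape != (m,):
            raise ValueError(f"expected length {m} vector, got {theta.shape}")
        h = theta[:n]
        J = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        J[iu] = theta[n:]
        J = J + J.T
        return cls(h=h, J=J)

    @classmethod
    def zeros(cls, n: int) -> "MEMParams":
        return cls(h=np.zeros(n), J=np.zeros((n, n)))


@dataclass
class Moments:
    """Empirical or model first/second moments of ±1 activity.

    ``first[i] = ⟨σ_i⟩`` and ``second[i, j] = ⟨σ_i σ_j⟩`` (diagonal ≡ 1);
    ``t_max`` records how many samples the moments summarize (used for
    pseudo-count clipping during fitting; may be ``None`` for exact moments).
    """

    first: np.ndarray
    second: np.ndarray
    t_max: int | None = None

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        n = self.first.shape[0]
        if self.second.shape != (n, n):
            raise ValueError("second-moment matrix shape mismatch")
        if np.any(np.abs(self.first) > 1 + 1e-9) or np.any(np.abs(self.second) > 1 + 1e-9):
            raise ValueError("moments of ±1 variables must lie in [-1, 1]")
        if not np.allclose(np.diag(self.second), 1.0, atol=1e-9):
            raise ValueError("diagonal of the second-moment matrix must be 1")

    @property
    def n(self) -> int:
        return self.first.shape[0]

    def flatten(self) -> np.ndarray:
        """Canonical M-vector (⟨σ_1⟩..⟨σ_N⟩, ⟨σ_1σ_2⟩, …, ⟨σ_{N−1}σ_N⟩)."""
        iu = np.triu_indices(self.n, k=1)
        return np.concatenate([self.first, self.second[iu]])


@dataclass
class PatternDistribution:
    """Probability distribution over the 2^N activity patterns.

    ``probs[k]`` is the probability of state ``k`` in the little-endian
    encoding of :func:`state_patterns`.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -1e-15):
            raise ValueError("probabilities must be nonnegative")
        s = self.probs.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1 (got {s!r})")

    @property
    def n(self) -> int:
        n = int(round(np.log2(self.probs.shape[0])))
        if 2**n != self.probs.shape[0]:
            raise ValueError("length must be a power of two")
        return n


@dataclass
class FitResult:
    """Outcome of iterative likelihood maximization."""

    params: MEMParams
    n_iterations: int
    converged: bool
    final_moment_error: float
    learning_rate: float
    tol: float = field(default=1e-6)


# ---------------------------------------------------------------------------
# energies and probabilities


def energy(params: MEMParams, pattern: np.ndarray) -> float:
    """Energy of a single ±1 pattern: −h·σ − Σ_{i<j} J_ij σ_i σ_j."""
    sigma = np.asarray(pattern, dtype=float)
    if sigma.shape != (params.n,):
        raise ValueError(f"pattern length {sigma.shape} does not match N={params.n}")
    return float(-params.h @ sigma - 0.5 * sigma @ params.J @ sigma)


def energies(params: MEMParams) -> np.ndarray:
    """Energies of all 2^N patterns in canonical state order."""
    pats = state_patterns(params.n).astype(float)
    return -pats @ params.h - 0.5 * np.einsum("ki,ij,kj->k", pats, params.J, pats)


def pattern_probabilities(params: MEMParams) -> PatternDistribution:
    """Boltzmann distribution P(V) ∝ exp(−E(V)), overflow-guarded."""
    e = energies(params)
    w = np.exp(-(e - e.min()))
    return PatternDistribution(probs=w / w.sum())


# ---------------------------------------------------------------------------
# moments


def empirical_moments(values: np.ndarray) -> Moments:
    """Time-averaged first and second moments of an (N, tmax) ±1 array."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected an (N, tmax) array")
    t_max = v.shape[1]
    first = v.mean(axis=1)
    second = (v @ v.T) / t_max
    np.fill_diagonal(second, 1.0)
    return Moments(first=first, second=second, t_max=t_max)


def empirical_distribution(values: np.ndarray) -> PatternDistribution:
    """Normalized pattern counts of an (N, tmax) ±1 array."""
    v = np.asarray(values)
    n, t_max = v.shape
    _check_enum(n)
    bits = (v > 0).astype(np.int64)
    idx = bits.T @ (1 << np.arange(n, dtype=np.int64))
    counts = np.bincount(idx, minlength=2**n)
    return PatternDistribution(probs=counts / t_max)


def moments_from_distribution(dist: PatternDistribution) -> Moments:
    """Exact first and second moments of a pattern distribution."""
    n = dist.n
    pats = state_patterns(n).astype(float)
    first = pats.T @ dist.probs
    second = (pats * dist.probs[:, None]).T @ pats
    np.fill_diagonal(second, 1.0)
    return Moments(first=first, second=second, t_max=None)


def model_moments(params: MEMParams) -> Moments:
    """Exact moments ⟨σ_i⟩_m, ⟨σ_i σ_j⟩_m under the Boltzmann distribution."""
    return moments_from_distribution(pattern_probabilities(params))


# ---------------------------------------------------------------------------
# fitting


def _prob_scale(m: Moments) -> tuple[np.ndarray, np.ndarray]:
    """Map ±1 moments to probability scale: p = (⟨σ⟩ + 1)/2 ∈ [0, 1]."""
    return (m.first + 1.0) / 2.0, (m.second + 1.0) / 2.0


def _clip_probs(p: np.ndarray, t_max: int | None) -> np.ndarray:
    """Pseudo-count guard against exactly saturated empirical moments."""
    if t_max is None:
        eps = 1e-12
    else:
        eps = 1.0 / (2.0 * t_max)
    if np.any(p < eps) or np.any(p > 1 - eps):
        warnings.warn(
            "degenerate probability-scale moments clipped away from {0, 1}",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.clip(p, eps, 1 - eps)


def fit_likelihood_max(
    moments: Moments,
    eps: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 500_000,
    mode: str = "multiplicative",
) -> FitResult:
    """Fit (h, J) by iterative moment matching (gradient ascent on likelihood).

    The classical update adds ``ε·log(⟨σ⟩/⟨σ⟩_m)`` to each parameter, which is
    ill-defined when a ±1-coded moment is zero or negative; the default
    ``multiplicative`` mode therefore applies the identical log-ratio update on
    probability-scale moments ``p = (⟨σ⟩+1)/2 ∈ (0, 1)``, which has the same
    fixed point (model moments = empirical moments).  ``additive`` mode uses
    the plain gradient ``ε·(⟨σ⟩ − ⟨σ⟩_m)`` instead.

    Convergence is declared when the max-abs probability-scale moment mismatch
    falls below ``tol``; non-convergence is reported on the result, not raised.
    """
    n = moments.n
    _check_enum(n)
    iu = np.triu_indices(n, k=1)
    p1_emp, p2_emp = _prob_scale(moments)
    p1_emp = _clip_probs(p1_emp, moments.t_max)
    p2_up = _clip_probs(p2_emp[iu], moments.t_max)

    h = np.zeros(n)
    Jup = np.zeros(len(iu[0]))
    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        J = np.zeros((n, n))
        J[iu] = Jup
        params = MEMParams(h=h, J=J + J.T)
        mm = model_moments(params)
        q1, q2 = _prob_scale(mm)
        q2_up = q2[iu]
        err = max(np.max(np.abs(q1 - p1_emp)), np.max(np.abs(q2_up - p2_up)))
        if err < tol:
            return FitResult(params, it, True, float(err), eps, tol)
        if mode == "multiplicative":
            h = h + eps * np.log(p1_emp / q1)
            Jup = Jup + eps * np.log(p2_up / q2_up)
        elif mode == "additive":
            h = h + eps * ((2 * p1_emp - 1) - (2 * q1 - 1))
            Jup = Jup + eps * ((2 * p2_up - 1) - (2 * q2_up - 1))
        else:
            raise ValueError(f"unknown update mode {mode!r}")
    J = np.zeros((n, n))
    J[iu] = Jup
    return FitResult(MEMParams(h=h, J=J + J.T), it, False, float(err), eps, tol)


def fit_independent(moments: Moments) -> MEMParams:
    """First-order (independent) model: J = 0, h_i = atanh(⟨σ_i⟩)."""
    m1 = moments.first
    sat = np.abs(m1) >= 1.0
    if np.any(sat):
        warnings.warn(
            "|⟨σ_i⟩| = 1 clipped before atanh (saturated moment)",
            RuntimeWarning,
            stacklevel=2,
        )
    t = moments.t_max or 10**12
    m1 = np.clip(m1, -1 + 1.0 / t, 1 - 1.0 / t)
    n = moments.n
    return MEMParams(h=np.arctanh(m1), J=np.zeros((n, n)))


# ---------------------------------------------------------------------------
# accuracy of fit


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback–Leibler divergence in bits with the 0·log0 = 0 convention."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def accuracy_rd(
    pn: PatternDistribution,
    p1: PatternDistribution,
    p2: PatternDistribution,
) -> float:
    """Accuracy-of-fit index r_D = (D1 − D2)/D1.

    ``D_ℓ`` is the KL divergence (bits) from the empirical distribution ``pn``
    to the ℓ-th order model distribution.  r_D = 1 when the pairwise model
    reproduces ``pn`` exactly and 0 when it fits no better than the
    independent model.  Returns NaN when D1 = 0 (the independent model already
    fits perfectly, so the ratio is undefined).
    """
    if np.any(p1.probs <= 0) or np.any(p2.probs <= 0):
        raise ValueError("model distributions must be strictly positive")
    d1 = _kl_bits(pn.probs, p1.probs)
    d2 = _kl_bits(pn.probs, p2.probs)
    if d1 == 0.0:
        return float("nan")
    return (d1 - d2) / d1
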