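"""Variational-Bayes estimation of session-wise Ising parameters.

Each session n carries its own parameter vector θ_n ∈ R^M (M = N(N+1)/2,
ordered h_1..h_N then J_12, J_13, …, J_{N−1,N}) with a shared Gaussian prior
θ_nM′ ~ N(η_M′, 1/α_M′).  The posterior is approximated by an independent
Gaussian q(θ_nM′) = N(μ_nM′, 1/β_nM′) whose closed-form updates are

    μ_n = η + tmax · A⁻¹ (⟨σ̄_n⟩ − ⟨σ̄⟩_η),   A = diag(α) + tmax·C_η,
    β_n = α + tmax · c_η,

where ⟨σ̄⟩_η and C_η are the exact mean and covariance of the moment vector
σ̄ under the Boltzmann distribution at η and c_η = diag(C_η).  The
hyperparameters are then re-estimated empirically (empirical Bayes):

    η = mean_n μ_n,    α = 1 / mean_n[(μ_n − η)² + 1/β_n].

The two steps alternate until the relative ELBO change drops below 1e−8.
The ELBO itself uses a second-order expansion of the log partition function
around the posterior mean (curvature evaluated at η, consistent with the
update equations) plus the exact Gaussian KL(q ‖ prior):

    ELBO = Σ_n [ tmax(μ_n·⟨σ̄_n⟩ − log Z(μ_n)) − (tmax/2) Σ_M′ c_η,M′/β_nM′
                 − KL(q_n ‖ N(η, diag(1/α))) ].

Borrowing strength across sessions lets single sessions too short for plain
likelihood maximization yield stable, session-specific landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from . import mem
from .mem import MEMParams, Moments
from .series import BinaryTimeSeries

__all__ = [
    "BayesHyper",
    "BayesPosterior",
    "session_moment_vector",
    "model_mean_and_cov",
    "posterior_update",
    "hyper_update",
    "vb_fit",
    "MAX_VB_N",
]

#: Exact-enumeration limit for the variational-Bayes moment computations.
MAX_VB_N = 12


@lru_cache(maxsize=16)
def _features(n: int) -> np.ndarray:
    """(2^N, M) matrix of σ̄(V) = (σ_1..σ_N, σ_1σ_2, …, σ_{N−1}σ_N) per state."""
    pats = mem.state_patterns(n).astype(float)
    iu, ju = np.triu_indices(n, k=1)
    f = np.concatenate([pats, pats[:, iu] * pats[:, ju]], axis=1)
    f.setflags(write=False)
    return f


@dataclass
class BayesHyper:
    """Shared prior mean η and precision α over the M model parameters."""

    eta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.eta.shape != self.alpha.shape or self.eta.ndim != 1:
            raise ValueError("eta and alpha must be equal-length vectors")
        if np.any(self.alpha <= 0):
            raise ValueError("prior precisions must be positive")

    @property
    def m(self) -> int:
        return self.eta.shape[0]


@dataclass
class BayesPosterior:
    """Per-session Gaussian posteriors and the optimization trace."""

    mu: np.ndarray  # (D, M)
    beta: np.ndarray  # (D, M)
    elbo_trace: list[float] = field(default_factory=list)
    n_outer_iterations: int = 0
    converged: bool = True

    def session_params(self, n: int) -> list[MEMParams]:
        """Posterior-mean parameters of every session as MEMParams."""
        return [MEMParams.from_flat(row, n) for row in self.mu]


def session_moment_vector(b: BinaryTimeSeries | np.ndarray) -> np.ndarray:
    """Empirical moment vector ⟨σ̄_n⟩ in the canonical M-ordering."""
    values = b.values if isinstance(b, BinaryTimeSeries) else np.asarray(b)
    return mem.empirical_moments(values).flatten()


def model_mean_and_cov(eta: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and covariance of σ̄ under the Boltzmann model at η."""
    eta = np.asarray(eta, dtype=float)
    if n > MAX_VB_N:
        raise ValueError(f"N={n} exceeds the VB enumeration limit N<={MAX_VB_N}")
    f = _features(n)
    if eta.shape != (f.shape[1],):
        raise ValueError(f"eta must have length M={f.shape[1]}")
    logits = f @ eta
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    mean = f.T @ p
    cov = (f * p[:, None]).T @ f - np.outer(mean, mean)
    return mean, cov


def posterior_update(
    hyper: BayesHyper,
    session_moments: np.ndarray,
    t_max: int,
    model_mean: np.ndarray | None = None,
    model_cov: np.ndarray | None = None,
    n: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form posterior mean and precision for one session.

    The symmetric positive-definite system A μ̃ = (⟨σ̄_n⟩ − ⟨σ̄⟩_η) is solved
    by Cholesky factorization rather than explicit inversion.  ``model_mean``
    and ``model_cov`` may be precomputed (they depend only on η).
    """
    if model_mean is None or model_cov is None:
        if n is None:
            raise ValueError("pass n when model mean/cov are not precomputed")
        model_mean, model_cov = model_mean_and_cov(hyper.eta, n)
    if t_max == 0:
        return hyper.eta.copy(), hyper.alpha.copy()
    a = np.diag(hyper.alpha) + t_max * model_cov
    try:
        factor = cho_factor(a)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"posterior system numerically singular (cond≈{np.linalg.cond(a):.3g})"
        ) from exc
    mu = hyper.eta + t_max * cho_solve(factor, session_moments - model_mean)
    beta = hyper.alpha + t_max * np.diag(model_cov)
    return mu, beta


def hyper_update(mu: np.ndarray, beta: np.ndarray) -> BayesHyper:
    """Empirical-Bayes re-estimation of the prior from the posteriors."""
    mu = np.atleast_2d(mu)
    beta = np.atleast_2d(beta)
    eta = mu.mean(axis=0)
    alpha = 1.0 / np.mean((mu - eta) ** 2 + 1.0 / beta, axis=0)
    return BayesHyper(eta=eta, alpha=alpha)


def _elbo(
    hyper: BayesHyper,
    mu: np.ndarray,
    beta: np.ndarray,
    moment_vectors: np.ndarray,
    t_maxes: np.ndarray,
    n: int,
) -> float:
    f = _features(n)
    c_eta = np.diag(model_mean_and_cov(hyper.eta, n)[1])
    total = 0.0
    for row_mu, row_beta, m_n, t in zip(mu, beta, moment_vectors, t_maxes):
        log_z = logsumexp(f @ row_mu)
        ell = t * (row_mu @ m_n - log_z) - 0.5 * t * np.sum(c_eta / row_beta)
        kl = 0.5 * np.sum(
            np.log(row_beta / hyper.alpha)
            + hyper.alpha / row_beta
            + hyper.alpha * (row_mu - hyper.eta) ** 2
            - 1.0
        )
        total += ell - kl
    return float(total)


def vb_fit(
    sessions: list[BinaryTimeSeries | np.ndarray],
    seed: int | np.random.SeedSequence = 0,
    elbo_tol: float = 1e-8,
    max_outer: int = 10_000,
    alpha_h: float = 6.0,
    alpha_j: float = 30.0,
    eta_init_sd: float = 0.1,
) -> tuple[BayesHyper, BayesPosterior]:
    """Alternate posterior and hyperparameter updates until ELBO convergence.

    Initialization draws each prior mean entry from N(0, eta_init_sd²) and
    sets the prior precisions to ``alpha_h`` for the N bias entries and
    ``alpha_j`` for the M−N coupling entries.  Iteration stops when
    |ELBO(iter)/ELBO(iter−1) − 1| < ``elbo_tol`` or at ``max_outer`` (flagged
    as non-converged on the result).  Deterministic for fixed inputs/seed.
    """
    arrays = [s.values if isinstance(s, BinaryTimeSeries) else np.asarray(s) for s in sessions]
    if not arrays:
        raise ValueError("need at least one session")
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all sessions must share N")
    if n > MAX_VB_N:
        raise ValueError(f"N={n} exceeds the VB enumeration limit N<={MAX_VB_N}")
    m = n * (n + 1) // 2
    moment_vectors = np.array([session_moment_vector(a) for a in arrays])
    t_maxes = np.array([a.shape[1] for a in arrays], dtype=float)

    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, eta_init_sd, size=m)
    alpha = np.concatenate([np.full(n, alpha_h), np.full(m - n, alpha_j)])
    hyper = BayesHyper(eta=eta, alpha=alpha)

    trace: list[float] = []
    converged = False
    it = 0
    d = len(arrays)
    mu = np.zeros((d, m))
    beta = np.zeros((d, m))
    for it in range(1, max_outer + 1):
        mean, cov = model_mean_and_cov(hyper.eta, n)
        for k in range(d):
            mu[k], beta[k] = posterior_update(
                hyper, moment_vectors[k], int(t_maxes[k]), model_mean=mean, model_cov=cov
            )
        hyper = hyper_update(mu, beta)
        elbo = _elbo(hyper, mu, beta, moment_vectors, t_maxes, n)
        trace.append(elbo)
        if len(trace) >= 2 and abs(trace[-1] / trace[-2] - 1.0) < elbo_tol:
            converged = True
            break
    posterior = BayesPosterior(
        mu=mu.copy(),
        beta=beta.copy(),
        elbo_trace=trace,
        n_outer_iterations=it,
        converged=converged,
    )
    return hyper, posterior
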