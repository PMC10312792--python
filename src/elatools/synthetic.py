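"""Seeded generators of synthetic cohorts of binary and continuous series.

The generators emulate the structure of a multi-session resting-state study:
a grid of participants × sessions in which every session of participant p is
drawn from an Ising model with parameters

    θ_ps = θ_base + δ_p + δ_ps,

where δ_p ~ N(0, participant_sd²) per parameter entry is fixed across the
participant's sessions and δ_ps ~ N(0, session_sd²) varies per session.
Choosing participant_sd ≫ session_sd produces participant-specific
("fingerprint-like") landscapes — smaller within-participant than
between-participant discrepancy; participant_sd = 0 gives an exchangeable
cohort, the null of the reliability permutation test.

All randomness flows from one top-level seed through `numpy.random
.SeedSequence.spawn`, so per-participant and per-session streams are stable
under partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mem
from .mem import MEMParams
from .series import BinaryTimeSeries, ContinuousTimeSeries

__all__ = [
    "CohortSpec",
    "sample_binary_series",
    "sample_binary_series_glauber",
    "random_binary_series",
    "generate_cohort",
    "generate_continuous_cohort",
    "default_base_params",
]


@dataclass
class CohortSpec:
    """Design of a synthetic participants × sessions cohort."""

    n_participants: int
    n_sessions: int
    base_params: MEMParams
    t_max: int
    participant_sd: float = 0.0
    session_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_sessions < 1 or self.t_max < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.participant_sd < 0 or self.session_sd < 0:
            raise ValueError("perturbation standard deviations must be nonnegative")
        if self.base_params.n > mem.MAX_ENUM_N:
            raise ValueError(f"N must be <= {mem.MAX_ENUM_N} (exact-enumeration regime)")

    @property
    def n_rois(self) -> int:
        return self.base_params.n


def default_base_params(n_rois: int, coupling_scale: float = 0.3, seed: int = 1234) -> MEMParams:
    """A generic weak-coupling Ising model to use as a cohort base.

    Couplings are drawn once from N(0, coupling_scale²) (spin-glass-like mix
    of signs, as observed in models fitted to real recordings) and biases
    from N(0, (coupling_scale/3)²), i.e. near zero as they are for
    mean-thresholded data.
    """
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, coupling_scale / 3.0, size=n_rois)
    iu = np.triu_indices(n_rois, k=1)
    J = np.zeros((n_rois, n_rois))
    J[iu] = rng.normal(0.0, coupling_scale, size=len(iu[0]))
    return MEMParams(h=h, J=J + J.T)


def sample_binary_series(
    params: MEMParams, t_max: int, seed: int | np.random.SeedSequence | np.random.Generator
) -> BinaryTimeSeries:
    """Draw t_max i.i.d. ±1 patterns from the model's Boltzmann distribution.

    Sampling is exact: the 2^N state probabilities are enumerated and states
    drawn by inverse CDF.  The model itself is a static distribution, so
    i.i.d. columns match the estimators' use of time-aggregated moments.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = mem.pattern_probabilities(params)
    states = rng.choice(dist.probs.shape[0], size=t_max, p=dist.probs)
    values = mem.state_patterns(params.n)[states].T
    return BinaryTimeSeries(values=values)


def sample_binary_series_glauber(
    params: MEMParams,
    t_max: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    sweeps_per_sample: int = 1,
    burn_in: int = 100,
) -> BinaryTimeSeries:
    """Temporally correlated sampling by single-spin heat-bath (Glauber) dynamics.

    Optional alternative to the i.i.d. sampler for studying autocorrelated
    data; one recorded column per ``sweeps_per_sample`` full sweeps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n
    sigma = rng.integers(0, 2, size=n) * 2 - 1
    out = np.empty((n, t_max), dtype=np.int8)
    n_sweeps = burn_in + t_max * sweeps_per_sample
    col = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            field_i = params.h[i] + params.J[i] @ sigma - params.J[i, i] * sigma[i]
            p_up = 1.0 / (1.0 + np.exp(-2.0 * field_i))
            sigma[i] = 1 if rng.random() < p_up else -1
        if sweep >= burn_in and (sweep - burn_in + 1) % sweeps_per_sample == 0:
            out[:, col] = sigma
            col += 1
            if col == t_max:
                break
    return BinaryTimeSeries(values=out[:, :t_max])


def random_binary_series(
    n_rois: int, length: int, seed: int | np.random.SeedSequence | np.random.Generator
) -> BinaryTimeSeries:
    """Fair-coin ±1 series: every entry independently ±1 with probability 0.5."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return BinaryTimeSeries(values=rng.integers(0, 2, size=(n_rois, length)) * 2 - 1)


def _perturb(base: MEMParams, delta: np.ndarray) -> MEMParams:
    """Add an M-vector perturbation on the (h, upper-triangle J) scale."""
    return MEMParams.from_flat(base.flatten() + delta, base.n)


def cohort_params(spec: CohortSpec) -> dict[tuple[str, str], MEMParams]:
    """The generating parameters θ_ps of every cell, without sampling series."""
    ss = np.random.SeedSequence(spec.seed)
    part_seq, sess_seq = ss.spawn(2)
    m = spec.base_params.m
    out: dict[tuple[str, str], MEMParams] = {}
    part_streams = part_seq.spawn(spec.n_participants)
    sess_streams = sess_seq.spawn(spec.n_participants)
    for p in range(spec.n_participants):
        rng_p = np.random.default_rng(part_streams[p])
        delta_p = rng_p.normal(0.0, spec.participant_sd, size=m)
        cell_streams = sess_streams[p].spawn(spec.n_sessions)
        for s in range(spec.n_sessions):
            rng_ps = np.random.default_rng(cell_streams[s])
            delta_ps = rng_ps.normal(0.0, spec.session_sd, size=m)
            out[(f"p{p}", f"s{s}")] = _perturb(spec.base_params, delta_p + delta_ps)
    return out


def generate_cohort(spec: CohortSpec):
    """Sample a complete participants × sessions table of binary series.

    Returns a :class:`~elatools.reliability.SessionTable`; deterministic for
    a fixed ``spec.seed``.
    """
    from .reliability import SessionTable  # local import avoids a cycle

    params = cohort_params(spec)
    data_seq = np.random.SeedSequence((spec.seed, 1))
    streams = data_seq.spawn(len(params))
    grid = {}
    for (key, theta), stream in zip(sorted(params.items()), streams):
        b = sample_binary_series(theta, spec.t_max, stream)
        b.meta.update(participant_id=key[0], session_id=key[1])
        grid[key] = b
    participants = [f"p{p}" for p in range(spec.n_participants)]
    sessions = [f"s{s}" for s in range(spec.n_sessions)]
    return SessionTable(grid=grid, participants=participants, sessions=sessions)


def generate_continuous_cohort(
    spec: CohortSpec,
    noise_sd: float,
    global_signal_sd: float = 1.0,
):
    """Continuous cohort: latent ±1 activity plus noise and a global signal.

    Each cell's real-valued series is ``x_it = σ_it + g_t + ε_it`` with
    ε_it ~ N(0, noise_sd²) and a common time-varying offset
    g_t ~ N(0, global_signal_sd²) shared by all ROIs (a synthetic global
    signal).  Returns ``(continuous_table, latent_binary_table)`` where the
    latent table equals :func:`generate_cohort` at the same spec, so
    z-scoring + binarization recovery can be scored against the truth.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    latent = generate_cohort(spec)
    noise_seq = np.random.SeedSequence((spec.seed, 2))
    streams = noise_seq.spawn(len(latent.grid))
    grid = {}
    for (key, b), stream in zip(sorted(latent.grid.items()), streams):
        rng = np.random.default_rng(stream)
        g = rng.normal(0.0, global_signal_sd, size=b.t_max)
        x = b.values.astype(float) + g[None, :] + rng.normal(0.0, noise_sd, size=b.values.shape)
        grid[key] = ContinuousTimeSeries(values=x, roi_labels=list(b.roi_labels), meta=dict(b.meta))
    from .reliability import SessionTable

    cont = SessionTable(grid=grid, participants=list(latent.participants), sessions=list(latent.sessions))
    return cont, latent
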