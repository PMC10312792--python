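"""Pairwise maximum-entropy model: energies, probabilities, moments, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elatools import mem
from elatools.mem import (
    MEMParams,
    Moments,
    PatternDistribution,
    accuracy_rd,
    empirical_distribution,
    empirical_moments,
    fit_independent,
    fit_likelihood_max,
    model_moments,
    moments_from_distribution,
    pattern_probabilities,
    state_patterns,
)


class TestEnergy:
    @pytest.mark.parametrize(
        "h, J12, pattern, expected",
        [
            ([0, 0], 1.0, [1, 1], -1.0),
            ([0, 0], 0.0, [1, -1], 0.0),
            ([1, -1], 0.0, [1, 1], 0.0),
            ([0.5, 0.5], 1.0, [-1, -1], 0.0),
        ],
    )
    def test_hand_values(self, h, J12, pattern, expected):
        p = MEMParams(h=h, J=[[0, J12], [J12, 0]])
        assert mem.energy(p, np.array(pattern)) == pytest.approx(expected)

    def test_vectorized_matches_scalar(self, params3):
        e = mem.energies(params3)
        pats = state_patterns(3)
        for k in range(8):
            assert e[k] == pytest.approx(mem.energy(params3, pats[k]))

    def test_length_mismatch_raises(self, params3):
        with pytest.raises(ValueError):
            mem.energy(params3, np.array([1, -1]))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            MEMParams(h=[0, 0], J=[[0, 1], [2, 0]])  # asymmetric
        with pytest.raises(ValueError):
            MEMParams(h=[0, 0], J=[[1, 0], [0, 1]])  # nonzero diagonal


class TestPatternProbabilities:
    def test_single_spin_symmetry(self):
        d = pattern_probabilities(MEMParams(h=[0.0], J=[[0.0]]))
        assert np.allclose(d.probs, [0.5, 0.5])

    def test_two_spin_closed_form(self):
        d = pattern_probabilities(MEMParams(h=[0, 0], J=[[0, 1], [1, 0]]))
        z = 2 * math.e + 2 / math.e
        # states: 00=(−,−), 01=(+,−), 10=(−,+), 11=(+,+)
        assert d.probs[0] == pytest.approx(math.e / z)
        assert d.probs[3] == pytest.approx(math.e / z)
        assert d.probs[1] == pytest.approx(1 / (math.e * z))

    def test_overflow_guarded(self):
        n = 4
        J = np.full((n, n), 50.0)
        np.fill_diagonal(J, 0.0)
        d = pattern_probabilities(MEMParams(h=np.full(n, 50.0), J=J))
        assert np.all(np.isfinite(d.probs))
        assert d.probs.sum() == pytest.approx(1.0)

    def test_invariant_under_energy_offset(self, params3):
        e = mem.energies(params3)
        w1 = np.exp(-(e - e.min()))
        w2 = np.exp(-((e + 7.3) - (e + 7.3).min()))
        assert np.allclose(w1 / w1.sum(), w2 / w2.sum())


class TestMoments:
    def test_single_column(self):
        m = empirical_moments(np.array([[1], [-1]]))
        assert m.first[0] == 1 and m.first[1] == -1
        assert m.second[0, 1] == -1

    def test_two_columns(self):
        v = np.array([[1, -1], [1, -1]])
        m = empirical_moments(v)
        assert np.allclose(m.first, 0)
        assert m.second[0, 1] == pytest.approx(1.0)

    def test_empirical_distribution_support(self, rng):
        v = rng.integers(0, 2, size=(4, 50)) * 2 - 1
        d = empirical_distribution(v)
        assert d.probs.sum() == pytest.approx(1.0)
        assert np.count_nonzero(d.probs) <= 50

    def test_model_moments_match_hand_enumeration(self, params3):
        # independent oracle: direct sums over the 8 patterns
        probs = pattern_probabilities(params3).probs
        pats = state_patterns(3).astype(float)
        mm = model_moments(params3)
        for i in range(3):
            assert mm.first[i] == pytest.approx(np.sum(pats[:, i] * probs))
            for j in range(3):
                assert mm.second[i, j] == pytest.approx(
                    np.sum(pats[:, i] * pats[:, j] * probs)
                )

    def test_zero_params_zero_moments(self):
        mm = model_moments(MEMParams.zeros(3))
        assert np.allclose(mm.first, 0)
        assert np.allclose(mm.second - np.eye(3), 0)

    def test_two_spin_correlation_tanh(self):
        mm = model_moments(MEMParams(h=[0, 0], J=[[0, 1], [1, 0]]))
        assert mm.second[0, 1] == pytest.approx(math.tanh(1.0))


class TestFitLikelihoodMax:
    def test_recovers_params_from_exact_moments(self, params3):
        fit = fit_likelihood_max(model_moments(params3), tol=1e-9)
        assert fit.converged
        assert np.abs(fit.params.J - params3.J).max() < 1e-3
        assert np.abs(fit.params.h - params3.h).max() < 1e-3
        mm = model_moments(fit.params)
        target = model_moments(params3)
        assert np.abs(mm.first - target.first).max() < 1e-6
        assert fit.final_moment_error <= fit.tol

    def test_independent_data_yields_zero_couplings(self):
        # exact product distribution with ⟨σ⟩ = (tanh(0.4), tanh(−0.7), 0)
        h_true = np.array([0.4, -0.7, 0.0])
        m1 = np.tanh(h_true)
        second = np.outer(m1, m1)
        np.fill_diagonal(second, 1.0)
        fit = fit_likelihood_max(Moments(first=m1, second=second), tol=1e-9)
        assert fit.converged
        assert np.abs(fit.params.J).max() < 1e-4
        assert np.allclose(fit.params.h, h_true, atol=1e-4)

    def test_consistency_error_shrinks_with_sample_size(self):
        from elatools import sample_binary_series

        truth = MEMParams(
            h=np.array([0.1, -0.2, 0.05, 0.15, -0.1]),
            J=_random_symmetric(5, scale=0.4, seed=7),
        )
        errs = []
        for t_max in (10**3, 10**4, 10**5):
            b = sample_binary_series(truth, t_max, seed=42)
            fit = fit_likelihood_max(empirical_moments(b.values))
            errs.append(np.abs(fit.params.J - truth.J).mean())
        assert errs[0] > errs[1] > errs[2]

    def test_additive_mode_same_fixed_point(self, params3):
        fit = fit_likelihood_max(model_moments(params3), mode="additive", tol=1e-8)
        assert fit.converged
        assert np.abs(fit.params.J - params3.J).max() < 1e-3

    def test_nonconvergence_flagged_not_raised(self, params3):
        fit = fit_likelihood_max(model_moments(params3), max_iter=3)
        assert not fit.converged
        assert fit.n_iterations == 3

    def test_degenerate_moments_clipped_with_warning(self):
        v = np.ones((2, 10), dtype=int)  # fully saturated
        with pytest.warns(RuntimeWarning):
            fit = fit_likelihood_max(empirical_moments(v), max_iter=500)
        assert np.all(np.isfinite(fit.params.h))


class TestFitIndependent:
    def test_inverse_tanh(self):
        m1 = np.array([0.0, math.tanh(1.0)])
        second = np.outer(m1, m1)
        np.fill_diagonal(second, 1.0)
        p = fit_independent(Moments(first=m1, second=second))
        assert p.h[0] == pytest.approx(0.0)
        assert p.h[1] == pytest.approx(1.0)
        assert np.all(p.J == 0)

    def test_first_moments_match_exactly(self, params3):
        m = model_moments(params3)
        p = fit_independent(m)
        assert np.allclose(model_moments(p).first, m.first, atol=1e-12)

    def test_saturated_moment_clipped(self):
        m1 = np.array([1.0, 0.0])
        second = np.eye(2)
        second[0, 1] = second[1, 0] = 0.0
        with pytest.warns(RuntimeWarning):
            p = fit_independent(Moments(first=m1, second=second, t_max=100))
        assert np.isfinite(p.h[0])


class TestAccuracyRd:
    def test_perfect_pairwise_fit_gives_one(self, params3):
        pn = pattern_probabilities(params3)
        m = moments_from_distribution(pn)
        p2 = pattern_probabilities(fit_likelihood_max(m, tol=1e-10).params)
        p1 = pattern_probabilities(fit_independent(m))
        assert accuracy_rd(pn, p1, p2) == pytest.approx(1.0, abs=1e-6)

    def test_parity_distribution_gives_zero(self):
        # uniform on the four N=3 patterns with σ1σ2σ3 = +1: pure third-order
        # structure; all first/second moments vanish so both fitted models are
        # uniform and D1 = D2 = 1 bit
        pats = state_patterns(3)
        probs = np.where(pats.prod(axis=1) == 1, 0.25, 0.0)
        pn = PatternDistribution(probs=probs)
        m = moments_from_distribution(pn)
        assert np.allclose(m.first, 0) and np.allclose(m.second - np.eye(3), 0)
        p2 = pattern_probabilities(fit_likelihood_max(m, tol=1e-10).params)
        p1 = pattern_probabilities(fit_independent(m))
        d1 = np.sum(pn.probs[pn.probs > 0] * np.log2(pn.probs[pn.probs > 0] * 8))
        assert d1 == pytest.approx(1.0)  # hand KL: 1 bit
        assert accuracy_rd(pn, p1, p2) == pytest.approx(0.0, abs=1e-9)

    def test_intermediate_fit_strictly_between(self, rng):
        from elatools import sample_binary_series

        truth = MEMParams(h=np.zeros(3), J=_random_symmetric(3, scale=0.8, seed=3))
        b = sample_binary_series(truth, 5000, seed=9)
        pn = empirical_distribution(b.values)
        m = empirical_moments(b.values)
        p2 = pattern_probabilities(fit_likelihood_max(m).params)
        p1 = pattern_probabilities(fit_independent(m))
        rd = accuracy_rd(pn, p1, p2)
        assert 0.0 < rd < 1.0

    def test_rd_larger_for_pairwise_generated_data(self):
        from elatools import sample_binary_series

        strong = MEMParams(h=np.zeros(3), J=_random_symmetric(3, scale=1.0, seed=5))
        indep = MEMParams(h=model_moments(strong).first * 0.0, J=np.zeros((3, 3)))

        def rd_of(truth, seed):
            b = sample_binary_series(truth, 20_000, seed=seed)
            pn = empirical_distribution(b.values)
            m = empirical_moments(b.values)
            p2 = pattern_probabilities(fit_likelihood_max(m).params)
            p1 = pattern_probabilities(fit_independent(m))
            return accuracy_rd(pn, p1, p2)

        assert rd_of(strong, 11) > rd_of(indep, 11)

    def test_undefined_when_independent_model_exact(self):
        pn = pattern_probabilities(MEMParams(h=[0.5], J=[[0.0]]))
        m = moments_from_distribution(pn)
        p1 = pattern_probabilities(fit_independent(m))
        assert math.isnan(accuracy_rd(pn, p1, p1))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    h=st.lists(st.floats(-2, 2), min_size=3, max_size=3),
    jvals=st.lists(st.floats(-2, 2), min_size=3, max_size=3),
)
def test_probabilities_normalized_and_rd_bounded(h, jvals):
    """Boltzmann probabilities normalize; r_D never exceeds 1."""
    J = np.zeros((3, 3))
    J[np.triu_indices(3, 1)] = jvals
    params = MEMParams(h=np.array(h), J=J + J.T)
    d = pattern_probabilities(params)
    assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
    m = moments_from_distribution(d)
    p1 = pattern_probabilities(fit_independent(m))
    rd = accuracy_rd(d, p1, d)
    assert math.isnan(rd) or rd <= 1.0 + 1e-12


def _random_symmetric(n: int, scale: float, seed: int) -> np.ndarray:
    r = np.random.default_rng(seed)
    J = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    J[iu] = r.normal(0, scale, size=len(iu[0]))
    return J + J.T
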