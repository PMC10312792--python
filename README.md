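# elatools

Energy-landscape analysis of binarized multichannel time series, with a
permutation test of test–retest reliability.

Resting-state brain activity (and other multichannel recordings) can be
summarized by a **pairwise maximum-entropy model** (an Ising model): each of
N channels is binarized to ±1, and the distribution of the 2^N activity
patterns is modeled as a Boltzmann distribution

    P(V) ∝ exp(−E(V)),    E(V) = − Σᵢ hᵢ σᵢ − ½ ΣᵢΣⱼ Jᵢⱼ σᵢ σⱼ,

fit so that the model reproduces the empirical first moments ⟨σᵢ⟩ and second
moments ⟨σᵢσⱼ⟩.  The fitted energy E(V) defines an **energy landscape** on the
N-dimensional hypercube whose local minima act as attractor states; the
minimax barrier between minima yields a **disconnectivity graph** (merge
tree), and gradient descent on the landscape partitions all patterns into
**basins of attraction**.

`elatools` implements that pipeline end to end:

- **Preprocessing** — z-scoring across channels at each time point (removes
  any common global signal) and binarization at each channel's time mean.
- **Fitting** — likelihood maximization by iterative moment matching (exact
  enumeration, N ≤ 15), plus an accuracy index r_D comparing the pairwise fit
  against the independent baseline; and a session-wise **variational-Bayes**
  estimator that shares an empirical-Bayes Gaussian prior across sessions
  (N ≤ 12).
- **Landscape** — local minima, threshold (barrier) energies via union–find,
  branch lengths, chance-level pruning of minor minima, basins, merge tree
  (JSON and Graphviz DOT).
- **Discrepancy** — four indices between two landscapes: dJ (mean absolute
  coupling difference), dH (mean Hamming distance between optimally matched
  minima), dbasin (mean cosine distance between matched basin-average
  activity vectors) and dL (relative difference of mean branch lengths).
- **Reliability** — within-participant (d1) vs between-participant (d2)
  discrepancies over a participants × sessions grid, the ratio ND = d2/d1,
  and a permutation test of ND against cell exchangeability (pairwise and
  concatenated designs).
- **Synthetic data** — hierarchical Ising cohorts (participant- and
  session-level parameter perturbations) and continuous cohorts with a
  shared global signal, for validation and power analysis.
- **I/O and CLI** — delimited series files, YAML cohort manifests, JSON
  parameter files, and an `elatools` command-line wrapper.

## Worked example

Fit a model to simulated data and test reliability (see `examples/` for
runnable versions of each step):

```python
from elatools import (CohortSpec, default_base_params, generate_cohort,
                      permutation_test)

spec = CohortSpec(
    n_participants=6, n_sessions=4,
    base_params=default_base_params(n_rois=5, seed=1),
    t_max=2000,
    participant_sd=0.2,   # stable individual differences
    session_sd=0.02,      # small day-to-day drift
    seed=123,
)
cohort = generate_cohort(spec)
result = permutation_test(cohort, design="pairwise", measure="dJ", c=500, seed=5)
print(result.nd_observed, result.p_text())
```

Running `python examples/04_reliability_test.py` prints:

```
d1 (within-participant)  = 0.0417
d2 (between-participant) = 0.2513
ND = d2/d1 = 6.025  (p < 0.002, 500 permutations)

exchangeable control: ND = 0.973  (p = 0.75)
```

The structured cohort is detected (within-participant landscapes are six
times more similar than between-participant ones); the exchangeable control
cohort is correctly not flagged.  Single-model fitting
(`python examples/01_fit_and_accuracy.py`):

```
converged in 157 iterations (final moment error 9.54e-07)
mean |J_hat - J| = 0.0069
accuracy rD = 0.9986  (1 = perfect pairwise fit)
```

## Command line

```bash
elatools simulate -p 6 -s 4 -n 5 -t 2000 --participant-sd 0.2 --seed 1 --out cohort/
elatools fit cohort/p0_s0.csv --out model.json
elatools landscape model.json --out tree.json --dot tree.dot
elatools compare model_a.json model_b.json
elatools reliability --manifest cohort/manifest.yaml --measure dJ -c 1000 --out results/
```

## Documentation

- `docs/methods.md` — model, estimators, landscape constructions, the
  discrepancy measures and the permutation design, with all numerical
  defaults and their rationale.
- `examples/` — short narrative scripts, one per capability.
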