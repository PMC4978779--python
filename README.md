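# pofm — proportional-odds finite-mixture biclustering of ordinal data

`pofm` is model-based clustering for two-mode ordinal data: an `n x p`
matrix whose entries are ordered categorical responses coded `1..q` —
typically `n` subjects answering `p` Likert-scale questionnaire items.  It
simultaneously clusters the rows and/or the columns of the matrix while
fully respecting the ordinal scale, and is aimed at psychometric,
biostatistical and survey applications where "which groups of respondents
answer which groups of items more highly?" is the scientific question.

## The model

Each cell follows a cumulative-logit proportional-odds (PO) model.  With
cutpoints `mu_1 < ... < mu_{q-1}` and a cell in row cluster `r` and column
cluster `c`:

    logit P(Y_ij <= k) = mu_k - alpha_r - beta_c - gamma_rc ,   1 <= k < q,

with identifiability constraints `alpha_1 = beta_1 = 0` and the interaction
`gamma` doubly centred (each row and column of `gamma` sums to zero; the
additive model drops `gamma`).  Rows belong to one of `R` latent clusters
with mixing proportions `pi`, columns to one of `C` clusters with
proportions `kappa`; either mode may instead be a single homogeneous group
or fully saturated (every row/column its own group), giving the familiar
ladder of one-mode and two-mode (bi-)clustering models with

    nu = (q-1) + 2R + 2C - 4            (additive biclustering)
    nu = (q-1) + RC + R + C - 3         (with interaction)

free parameters, and so on for the other structures.

Fitting is by EM, treating memberships as missing data.  One-mode models
use the exact posterior; two-mode models use the mean-field variational
approximation of Govaert & Nadif, tracking the free energy
`F = l_c + H(zhat) + H(xhat)`.  The M-step maximises the expected
complete-data log-likelihood by a quasi-Newton search with analytic
gradients (cutpoint order enforced by a log-increment transform), and the
EM is restarted from multiple random fuzzy memberships because the surface
is multimodal.  Ten information criteria (AIC, AICc, AICu, CAIC, BIC, AIC3,
CLC, NEC, ICL-BIC, AWE) are available for choosing `(R, C)`; the plain Rand
index scores partition recovery in simulation.

## Worked example

```python
import numpy as np
from pofm import (ModelSpec, Parameters, SimulationConfig, equal_probability_cutpoints,
                  generate_dataset, fit, hard_assignment, rand_index)

truth = Parameters(
    mu=equal_probability_cutpoints(3),          # [-0.693, 0.693]: equal category probs
    alpha=np.array([0.0, 1.0, 2.0]),            # three row clusters
    beta=np.array([0.0, -1.0]),                 # two column clusters
    pi=np.full(3, 1/3), kappa=np.array([0.5, 0.5]),
)
spec = ModelSpec("clustered", "clustered", R=3, C=2)
config = SimulationConfig(99, 100, 3, spec, truth, "deterministic_blocks")
data, row_truth, col_truth = generate_dataset(config, seed=17)

result = fit(data, spec, n_starts=5, seed=2, tol=1e-7)
print(round(result.loglik, 1), result.nu)
print(rand_index(hard_assignment(result.posteriors.zhat), row_truth))
```

prints

```
-9669.7 8
1.0
```

i.e. the maximised log-likelihood of the 8-parameter additive biclustering
model and a row Rand index of 1.0: at this sample size every row pair is
correctly co-clustered or correctly separated relative to the generating
partition.  The fitted effects on this draw are
`alpha = (0, -1.006, -2.006)`, `beta = (0, -0.975)` — the magnitudes of the
generating effects to within about 0.03; fitted clusters are reported
sorted by decreasing effect with the first as baseline, so recovery studies
first re-align labels to the truth (`pofm.align_labels`).

A command-line interface wraps the same operations:

```sh
pofm simulate --n 99 --p 100 --q 3 --R 3 --alpha 0,1,2 --seed 17 --out sim/
pofm fit sim/data.csv --q 3 --rows clustered --R 3 --cols clustered --C 2 --out fit/
pofm select sim/data.csv --q 3 --rmax 4 --cmax 3 --criterion aic3 --out sel/
pofm study selection --reps 20 --seed 1 --out study/
```

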