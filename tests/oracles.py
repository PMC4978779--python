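"""Brute-force reference implementations used only by the tests.

These enumerate latent partitions directly (exponential cost) and stay
deliberately independent of the package's vectorised code paths.
"""

from itertools import combinations, product

import numpy as np
from scipy.special import expit, logsumexp


def po_probs(mu, eta):
    """Direct cumulative-difference PO probabilities (no log-space tricks)."""
    mu = np.asarray(mu, float)
    cum = np.concatenate([[0.0], expit(mu - eta), [1.0]])
    return np.diff(cum)


def loglik_joint_enumeration(values, q, mu, alpha, beta, pi, kappa):
    """Incomplete-data log-likelihood by summing over all joint row x column partitions."""
    n, p = values.shape
    R, C = len(alpha), len(beta)
    logth = np.log(
        np.array([[po_probs(mu, a + b) for b in beta] for a in alpha])
    )  # (R, C, q)
    terms = []
    for ra in product(range(R), repeat=n):
        for ca in product(range(C), repeat=p):
            t = sum(np.log(pi[r]) for r in ra) + sum(np.log(kappa[c]) for c in ca)
            for i in range(n):
                for j in range(p):
                    t += logth[ra[i], ca[j], values[i, j] - 1]
            terms.append(t)
    return logsumexp(terms)


def loglik_row_enumeration(values, q, mu, alpha, col_groups, beta, pi):
    """Row-mixture log-likelihood by summing over all row assignments."""
    n, p = values.shape
    R = len(alpha)
    logth = np.log(
        np.array([[po_probs(mu, a + b) for b in beta] for a in alpha])
    )
    terms = []
    for ra in product(range(R), repeat=n):
        t = sum(np.log(pi[r]) for r in ra)
        for i in range(n):
            for j in range(p):
                t += logth[ra[i], col_groups[j], values[i, j] - 1]
        terms.append(t)
    return logsumexp(terms)


def rand_index_pairs(labels_a, labels_b):
    """Rand index by direct enumeration of all item pairs."""
    idx = range(len(labels_a))
    agree = 0
    total = 0
    for i, j in combinations(idx, 2):
        total += 1
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        agree += same_a == same_b
    return agree / total


def count_free_values(params, spec):
    """Count free entries in a parameter container under the constraints."""
    nu = params.mu.size
    nu += params.alpha.size - 1
    nu += params.beta.size - 1
    if params.gamma is not None:
        nu += (params.gamma.shape[0] - 1) * (params.gamma.shape[1] - 1)
    if params.pi is not None:
        nu += params.pi.size - 1
    if params.kappa is not None:
        nu += params.kappa.size - 1
    return nu
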