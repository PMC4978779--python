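"""Partition agreement and label-alignment utilities.

The clustering studies score recovered partitions with the (plain) Rand
index: the fraction of item pairs on which two partitions agree, a pair
agreeing when it is co-clustered in both partitions or separated in both.
Mixture labels are arbitrary, so parameter summaries first align the
estimated groups to the generating truth by the permutation minimising the
total absolute effect discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .po_core import Parameters

__all__ = ["Partition", "hard_assignment", "rand_index", "adjusted_rand_index", "align_labels"]


@dataclass(frozen=True)
class Partition:
    """Group labels (1-based) over items, with a declared group count ``k``.

    ``k`` may exceed the number of occupied groups: emptied mixture
    components keep their index.
    """

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if labels.size and (labels.min() < 1 or labels.max() > self.k):
            raise ValueError(f"labels must lie in [1, {self.k}]")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.labels.size


def hard_assignment(posteriors: np.ndarray) -> Partition:
    """Argmax membership per item; exact ties go to the lowest group index."""
    m = np.asarray(posteriors, dtype=float)
    return Partition(labels=np.argmax(m, axis=1) + 1, k=m.shape[1])


def _pair_counts(a: Partition, b: Partition) -> tuple[float, float]:
    """(number of concordant pairs, total pairs) via the contingency table."""
    if a.n != b.n:
        raise ValueError(f"partition lengths differ: {a.n} vs {b.n}")
    if a.n < 2:
        raise ValueError("pairwise agreement needs at least two items")
    cont = np.zeros((a.k, b.k))
    np.add.at(cont, (a.labels - 1, b.labels - 1), 1.0)
    n = a.n
    total = n * (n - 1) / 2.0
    same_both = (cont * (cont - 1) / 2.0).sum()
    same_a = (cont.sum(axis=1) * (cont.sum(axis=1) - 1) / 2.0).sum()
    same_b = (cont.sum(axis=0) * (cont.sum(axis=0) - 1) / 2.0).sum()
    concordant = total + 2 * same_both - same_a - same_b
    return concordant, total


def rand_index(a: Partition, b: Partition) -> float:
    """Plain Rand index: fraction of pairs co-clustered in both or separated in both."""
    concordant, total = _pair_counts(a, b)
    return float(concordant / total)


def adjusted_rand_index(a: Partition, b: Partition) -> float:
    """Chance-corrected Rand index (extra; the replication outputs use the plain index)."""
    if a.n != b.n:
        raise ValueError(f"partition lengths differ: {a.n} vs {b.n}")
    cont = np.zeros((a.k, b.k))
    np.add.at(cont, (a.labels - 1, b.labels - 1), 1.0)
    nij = (cont * (cont - 1) / 2.0).sum()
    ai = (cont.sum(axis=1) * (cont.sum(axis=1) - 1) / 2.0).sum()
    bj = (cont.sum(axis=0) * (cont.sum(axis=0) - 1) / 2.0).sum()
    total = a.n * (a.n - 1) / 2.0
    expected = ai * bj / total
    max_index = (ai + bj) / 2.0
    if max_index == expected:
        return 1.0
    return float((nij - expected) / (max_index - expected))


def align_labels(estimate: Parameters, truth: Parameters) -> Parameters:
    """Permute the estimate's clusters to best match the truth's effects.

    Row groups are matched on ``alpha`` and column groups on ``beta`` by
    exhaustive search over permutations, minimising the summed absolute
    discrepancy after re-imposing the baseline constraints (which also
    shifts the cutpoints, leaving cell probabilities untouched).
    """
    est = estimate.copy()
    if est.alpha.size != truth.alpha.size or est.beta.size != truth.beta.size:
        raise ValueError("estimate and truth must have the same group counts")

    def best_perm(eff_est: np.ndarray, eff_true: np.ndarray) -> tuple[int, ...]:
        best, best_cost = None, np.inf
        for perm in permutations(range(eff_est.size)):
            rel = eff_est[list(perm)]
            cost = np.abs((rel - rel[0]) - (eff_true - eff_true[0])).sum()
            if cost < best_cost - 1e-15:
                best, best_cost = perm, cost
        return best

    if est.alpha.size > 1:
        perm = list(best_perm(est.alpha, truth.alpha))
        shift = est.alpha[perm[0]]
        est.mu = est.mu - shift
        est.alpha = est.alpha[perm] - shift
        if est.pi is not None:
            est.pi = est.pi[perm]
        if est.gamma is not None:
            est.gamma = est.gamma[perm, :]
    if est.beta.size > 1:
        perm = list(best_perm(est.beta, truth.beta))
        shift = est.beta[perm[0]]
        est.mu = est.mu - shift
        est.beta = est.beta[perm] - shift
        if est.kappa is not None:
            est.kappa = est.kappa[perm]
        if est.gamma is not None:
            est.gamma = est.gamma[:, perm]
    return est
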