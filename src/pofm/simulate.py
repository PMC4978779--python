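"""Synthetic ordinal matrices and the simulation studies.

The generator draws each cell of an ``n x p`` matrix independently from the
categorical distribution implied by the proportional-odds model at that
cell's (row group, column group) pair.  Row and column memberships come
either from contiguous deterministic blocks (sizes ``round(prop * n)``, the
last block absorbing the rounding remainder) or from multinomial draws with
the mixing proportions.

Two study drivers replicate the published designs at configurable scale:

* a model-selection study — five scenarios differing in their mixing
  proportions, data generated from an additive (R=3, C=2) biclustering
  truth with n=150, p=15, q=4, a grid of additive biclustering models
  fitted to each replicate, and each criterion scored on how often it
  recovers the generating (R, C);
* a recovery study — repeated generate/fit/align cycles recording the mean
  and standard error of the effect estimates and the Rand indices of the
  recovered hard partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import align_labels, hard_assignment, rand_index, Partition
from .inference import fit
from .po_core import (
    CLUSTERED,
    SINGLE,
    ModelSpec,
    OrdinalMatrix,
    Parameters,
    linear_predictor_grid,
)
from .selection import CRITERIA, criteria_table, _argmin_with_ties

__all__ = [
    "SimulationConfig",
    "equal_probability_cutpoints",
    "generate_dataset",
    "default_selection_scenarios",
    "run_selection_study",
    "run_recovery_study",
]

DETERMINISTIC = "deterministic_blocks"
MULTINOMIAL = "multinomial"


def equal_probability_cutpoints(q: int) -> np.ndarray:
    """Cutpoints ``mu_k = logit(k/q)`` giving equal category probabilities at eta=0.

    For example q=3 gives ``(log(1/2), log 2)`` and q=5 gives
    ``(log(1/4), log(2/3), log(3/2), log 4)``.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    k = np.arange(1, q)
    return np.log(k / (q - k))


@dataclass
class SimulationConfig:
    """Generating truth for one synthetic-data scenario."""

    n: int
    p: int
    q: int
    spec: ModelSpec
    params: Parameters
    membership_mode: str = DETERMINISTIC
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.membership_mode not in (DETERMINISTIC, MULTINOMIAL):
            raise ValueError(f"unknown membership mode {self.membership_mode!r}")
        for name, props in (("pi", self.params.pi), ("kappa", self.params.kappa)):
            if props is not None and abs(float(np.sum(props)) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")


def _block_labels(proportions: np.ndarray, n: int) -> np.ndarray:
    """Contiguous block memberships: first block first, last absorbs the remainder."""
    sizes = [int(round(float(w) * n)) for w in proportions[:-1]]
    sizes.append(n - sum(sizes))
    if min(sizes) < 0:
        raise ValueError("block proportions produce a negative block size")
    return np.repeat(np.arange(len(sizes)), sizes)


def _draw_memberships(
    spec_structure: str, k: int, count: int, props: np.ndarray | None,
    mode: str, rng: np.random.Generator,
) -> np.ndarray:
    if spec_structure == SINGLE or k == 1:
        return np.zeros(count, dtype=int)
    if spec_structure == "saturated":
        return np.arange(count)
    if mode == DETERMINISTIC:
        return _block_labels(np.asarray(props, float), count)
    return rng.choice(k, size=count, p=np.asarray(props, float))


def generate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[OrdinalMatrix, Partition, Partition]:
    """Simulate one matrix; returns the data and the true row/column partitions."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (in the config or as an argument)")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    spec, params = config.spec, config.params
    a = spec.n_row_groups(config.n)
    b = spec.n_col_groups(config.p)
    rg = _draw_memberships(spec.row_structure, a, config.n, params.pi, config.membership_mode, rng)
    cg = _draw_memberships(spec.col_structure, b, config.p, params.kappa, config.membership_mode, rng)
    eta = linear_predictor_grid(params, spec)
    from scipy.special import expit

    cum = expit(params.mu[None, None, :] - eta[:, :, None])  # (a, b, q-1)
    u = rng.random((config.n, config.p))
    y = 1 + (u[:, :, None] > cum[rg[:, None], cg[None, :], :]).sum(axis=2)
    data = OrdinalMatrix(y.astype(np.int64), config.q)
    return data, Partition(rg + 1, a), Partition(cg + 1, b)


# ---------------------------------------------------------------------------
# model-selection study


def default_selection_scenarios() -> list[dict]:
    """Five mixing-proportion scenarios for the (R=3, C=2) selection study.

    The published design describes the scenarios qualitatively (balanced /
    unbalanced / one proportion near zero); these are this package's
    concrete instantiations.
    """
    return [
        {"name": "S1", "pi": (0.2, 0.3, 0.5), "kappa": (0.7, 0.3)},
        {"name": "S2", "pi": (1 / 3, 1 / 3, 1 / 3), "kappa": (0.5, 0.5)},
        {"name": "S3", "pi": (0.6, 0.3, 0.1), "kappa": (0.5, 0.5)},
        {"name": "S4", "pi": (0.6, 0.3, 0.1), "kappa": (0.8, 0.2)},
        {"name": "S5", "pi": (0.85, 0.10, 0.05), "kappa": (0.5, 0.5)},
    ]


def _grid_specs(grid) -> list[ModelSpec]:
    """Additive biclustering candidates: (Rmax, Cmax) bounds or explicit (R, C) cells."""
    if len(grid) and isinstance(grid[0], (tuple, list)):
        cells = [(int(R), int(C)) for R, C in grid]
    else:
        r_max, c_max = grid
        cells = [(R, C) for R in range(1, r_max + 1) for C in range(1, c_max + 1)]
    return [
        ModelSpec(
            row_structure=CLUSTERED if R > 1 else SINGLE,
            col_structure=CLUSTERED if C > 1 else SINGLE,
            R=R if R > 1 else None,
            C=C if C > 1 else None,
        )
        for R, C in cells
    ]


def _classify(sel_R: int, sel_C: int, true_R: int, true_C: int) -> str:
    if (sel_R, sel_C) == (true_R, true_C):
        return "correct"
    if sel_R <= true_R and sel_C <= true_C:
        return "under"
    if sel_R >= true_R and sel_C >= true_C:
        return "over"
    return "mixed"


def _derived_seed(*tags: int) -> int:
    return int(np.random.SeedSequence(list(map(int, tags))).generate_state(1)[0] % (2**31))


def run_selection_study(
    scenarios: Sequence[dict] | None = None,
    reps: int = 20,
    grid: tuple[int, int] = (5, 5),
    n: int = 150,
    p: int = 15,
    q: int = 4,
    alpha: Sequence[float] = (0.0, 1.0, 2.0),
    beta: Sequence[float] = (0.0, -1.0),
    n_starts: int = 10,
    max_iter: int = 150,
    tol: float = 1e-6,
    seed: int = 0,
    membership_mode: str = MULTINOMIAL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score the ten criteria on recovering the generating (R, C).

    Returns ``(summary, detail)``: the summary averages the percentage of
    correct / under / over / mixed selections across scenarios (one row per
    criterion); the detail table has one row per scenario x criterion.
    Failed fits are logged in the detail table's ``n_failed`` column and
    excluded from the percentages.
    """
    if scenarios is None:
        scenarios = default_selection_scenarios()
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    true_R, true_C = alpha.size, beta.size
    mu = equal_probability_cutpoints(q)
    specs = _grid_specs(grid)
    RC = [(s.R or 1, s.C or 1) for s in specs]

    records = []
    for s_idx, scen in enumerate(scenarios):
        truth = Parameters(
            mu=mu.copy(), alpha=alpha.copy(), beta=beta.copy(),
            pi=np.asarray(scen["pi"], float), kappa=np.asarray(scen["kappa"], float),
        )
        config = SimulationConfig(
            n=n, p=p, q=q,
            spec=ModelSpec(CLUSTERED, CLUSTERED, R=true_R, C=true_C),
            params=truth, membership_mode=membership_mode,
        )
        counts = {crit: {"correct": 0, "under": 0, "over": 0, "mixed": 0} for crit in CRITERIA}
        n_failed = 0
        n_used = 0
        for rep in range(reps):
            data, _, _ = generate_dataset(config, seed=_derived_seed(seed, 11, s_idx, rep))
            try:
                table, _ = criteria_table(
                    data, specs, n_starts=n_starts, max_iter=max_iter, tol=tol,
                    seed=_derived_seed(seed, 13, s_idx, rep),
                )
            except Exception:
                n_failed += 1
                continue
            n_used += 1
            for crit in CRITERIA:
                try:
                    sel = RC[_argmin_with_ties(table, crit)]
                except ValueError:  # criterion undefined on the whole grid
                    counts[crit]["mixed"] += 1
                    continue
                counts[crit][_classify(sel[0], sel[1], true_R, true_C)] += 1
        for crit in CRITERIA:
            rec = {"scenario": scen.get("name", f"S{s_idx + 1}"), "criterion": crit,
                   "n_reps": n_used, "n_failed": n_failed}
            for kind in ("correct", "under", "over", "mixed"):
                rec[f"pct_{kind}"] = 100.0 * counts[crit][kind] / max(n_used, 1)
            records.append(rec)
    detail = pd.DataFrame(records)
    summary = (
        detail.groupby("criterion", sort=False)[["pct_correct", "pct_under", "pct_over", "pct_mixed"]]
        .mean()
        .reset_index()
    )
    return summary, detail


# ---------------------------------------------------------------------------
# parameter/partition recovery study


def run_recovery_study(
    configs: Sequence[SimulationConfig],
    reps: int = 100,
    n_starts: int = 10,
    max_iter: int = 150,
    tol: float = 1e-6,
    seed: int = 0,
    config_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate/fit/align repeatedly; summarise estimates and Rand indices.

    One output row per config with the mean and standard error of each free
    effect estimate (after label alignment to the truth) and the mean row
    and column Rand indices of the hard assignments against the generating
    partitions.
    """
    records = []
    for c_idx, config in enumerate(configs):
        spec = config.spec
        est_alpha, est_beta = [], []
        row_ri, col_ri = [], []
        n_failed = 0
        for rep in range(reps):
            data, row_truth, col_truth = generate_dataset(
                config, seed=_derived_seed(seed, 21, c_idx, rep)
            )
            try:
                fr = fit(
                    data, spec, n_starts=n_starts, max_iter=max_iter, tol=tol,
                    seed=_derived_seed(seed, 23, c_idx, rep),
                )
            except Exception:
                n_failed += 1
                continue
            aligned = align_labels(fr.params, config.params)
            est_alpha.append(aligned.alpha)
            est_beta.append(aligned.beta)
            if fr.posteriors.zhat is not None:
                row_ri.append(rand_index(hard_assignment(fr.posteriors.zhat), row_truth))
            elif spec.row_structure == SINGLE:
                row_ri.append(1.0 if row_truth.k == 1 else np.nan)
            if fr.posteriors.xhat is not None:
                col_ri.append(rand_index(hard_assignment(fr.posteriors.xhat), col_truth))
            elif spec.col_structure == SINGLE:
                col_ri.append(1.0 if col_truth.k == 1 else np.nan)
        rec: dict = {
            "config": config_names[c_idx] if config_names else f"config{c_idx + 1}",
            "n": config.n, "p": config.p, "q": config.q,
            "n_reps": reps - n_failed, "n_failed": n_failed,
        }
        if est_alpha:
            A = np.vstack(est_alpha)
            B = np.vstack(est_beta)
            m = A.shape[0]
            for r in range(1, A.shape[1]):
                rec[f"alpha{r + 1}_mean"] = A[:, r].mean()
                rec[f"alpha{r + 1}_se"] = A[:, r].std(ddof=1) / np.sqrt(m) if m > 1 else np.nan
            for c in range(1, B.shape[1]):
                rec[f"beta{c + 1}_mean"] = B[:, c].mean()
                rec[f"beta{c + 1}_se"] = B[:, c].std(ddof=1) / np.sqrt(m) if m > 1 else np.nan
        rec["row_rand_mean"] = float(np.mean(row_ri)) if row_ri else np.nan
        rec["col_rand_mean"] = float(np.mean(col_ri)) if col_ri else np.nan
        records.append(rec)
    return pd.DataFrame(records)
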