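"""Information criteria and grid-based model selection.

Ten likelihood-based criteria are supported, all on a smaller-is-better
scale.  With ``l`` the maximised incomplete-data log-likelihood, ``l_c`` the
maximised expected complete-data log-likelihood, ``EN = l - l_c`` the
membership entropy, ``nu`` the parameter count and ``N = np`` the number of
matrix cells:

    AIC      = -2 l + 2 nu
    AICc     = AIC + 2 nu (nu + 1) / (N - nu - 1)
    AICu     = AICc + N log(N / (N - nu - 1))
    CAIC     = -2 l + nu (1 + log N)
    BIC      = -2 l + nu log N
    AIC3     = -2 l + 3 nu
    CLC      = -2 l + 2 EN
    NEC      = EN / (l - l(1))        (l(1): the no-clustering null fit)
    ICL-BIC  = -2 l_c + nu log N
    AWE      = -2 l_c + 2 nu (3/2 + log N)

AICc/AICu are undefined when ``N <= nu + 1`` and NEC when ``l - l(1)`` is
not positive; undefined entries are NaN and excluded from selection.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .inference import FitResult, fit
from .po_core import ModelSpec, OrdinalMatrix

__all__ = ["CRITERIA", "compute_criteria", "criteria_table", "select_model"]

CRITERIA = ("aic", "aicc", "aicu", "caic", "bic", "aic3", "clc", "nec", "iclbic", "awe")


def compute_criteria(fit_result: FitResult, null_loglik: float, n: int, p: int) -> dict[str, float]:
    """All ten criterion values for one fitted model (NaN where undefined)."""
    ll = fit_result.loglik
    lc = fit_result.loglik_complete
    en = fit_result.entropy
    nu = fit_result.nu
    N = n * p
    logN = math.log(N)
    out = {
        "aic": -2 * ll + 2 * nu,
        "caic": -2 * ll + nu * (1 + logN),
        "bic": -2 * ll + nu * logN,
        "aic3": -2 * ll + 3 * nu,
        "clc": -2 * ll + 2 * en,
        "iclbic": -2 * lc + nu * logN,
        "awe": -2 * lc + 2 * nu * (1.5 + logN),
    }
    if N > nu + 1:
        out["aicc"] = out["aic"] + 2 * nu * (nu + 1) / (N - nu - 1)
        out["aicu"] = out["aicc"] + N * math.log(N / (N - nu - 1))
    else:
        out["aicc"] = math.nan
        out["aicu"] = math.nan
    gain = ll - null_loglik
    out["nec"] = en / gain if gain > 1e-12 else math.nan
    return {name: out[name] for name in CRITERIA}


def criteria_table(
    data: OrdinalMatrix,
    specs: Sequence[ModelSpec],
    null_loglik: float | None = None,
    **fit_options,
) -> tuple[pd.DataFrame, list[FitResult]]:
    """Fit every spec and tabulate ``nu``, ``l``, ``l_c``, ``EN`` and all criteria."""
    if null_loglik is None:
        null_loglik = fit(data, ModelSpec(), seed=fit_options.get("seed", 0)).loglik
    rows = []
    fits = []
    for spec in specs:
        fr = fit(data, spec, **fit_options)
        fits.append(fr)
        row = {
            "model": spec.label(),
            "row_structure": spec.row_structure,
            "col_structure": spec.col_structure,
            "R": spec.R,
            "C": spec.C,
            "interaction": spec.interaction,
            "nu": fr.nu,
            "loglik": fr.loglik,
            "loglik_flag": fr.loglik_flag,
            "loglik_complete": fr.loglik_complete,
            "entropy": fr.entropy,
            "converged": fr.converged,
        }
        row.update(compute_criteria(fr, null_loglik, data.n, data.p))
        rows.append(row)
    return pd.DataFrame(rows), fits


def _argmin_with_ties(table: pd.DataFrame, criterion: str) -> int:
    vals = table[criterion]
    if vals.isna().all():
        raise ValueError(f"criterion {criterion!r} is undefined for every candidate model")
    best = vals.min()
    cand = table[vals <= best + 1e-12].copy()
    # ties break toward the more parsimonious model
    cand = cand.sort_values(
        ["nu", "R", "C"], na_position="first", kind="stable"
    )
    return int(cand.index[0])


def select_model(
    data: OrdinalMatrix,
    specs: Sequence[ModelSpec],
    criterion: str = "aic3",
    **fit_options,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Pick the spec minimising one criterion over a candidate list.

    The null (no-clustering) fit needed by NEC is computed once and shared.
    Returns the winning spec together with the full audit table.
    """
    criterion = criterion.lower().replace("-", "").replace("_", "")
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    if not specs:
        raise ValueError("specs must be non-empty")
    table, _ = criteria_table(data, list(specs), **fit_options)
    return list(specs)[_argmin_with_ties(table, criterion)], table
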