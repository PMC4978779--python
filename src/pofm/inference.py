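"""Likelihoods and the EM algorithm for proportional-odds mixture models.

Membership of rows in row clusters and columns in column clusters is treated
as missing data.  For one-mode clustering the E-step posterior is exact and
the incomplete-data log-likelihood ``l`` marginalises the mixture by a
log-sum-exp over groups.  For two-mode (bi-)clustering the joint posterior
of row and column memberships does not factorise, so the E-step uses the
mean-field (variational) factorisation of Govaert & Nadif: alternating
multiplicative updates of ``zhat`` and ``xhat``, and the tracked objective is
the variational free energy

    F = l_c + H(zhat) + H(xhat) <= l,

where ``l_c`` is the expected complete-data log-likelihood and ``H`` the
membership entropy.  The exact ``l`` for a biclustering model sums over all
``C^p`` column assignments and is provided (guarded) for small problems.

The M-step maximises ``l_c`` over cutpoints and effects by a quasi-Newton
search with analytic gradients; cutpoint monotonicity is enforced through a
log-increment transform and the interaction's double sum-to-zero constraint
through its free ``(a-1) x (b-1)`` block.  Mixing proportions have closed
forms (posterior column means).  Inside the EM loop the maximiser is
warm-started from the previous parameters and capped at a small number of
quasi-Newton iterations (a generalised EM step); an explicit guard keeps
every accepted step an ascent step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .po_core import (
    ModelSpec,
    OrdinalMatrix,
    Parameters,
    Posteriors,
    InvalidSpecError,
    count_parameters,
    linear_predictor_grid,
    log_cell_probability_grid,
    validate_posteriors,
)

__all__ = [
    "FitResult",
    "fit",
    "e_step",
    "m_step",
    "complete_loglik",
    "incomplete_loglik",
    "incomplete_loglik_row_mixture",
    "incomplete_loglik_col_mixture",
    "incomplete_loglik_bicluster",
]

log = logging.getLogger("pofm.inference")

# probabilities are floored inside logs so that an emptied cluster or an
# essentially impossible cell cannot produce NaNs
_LOG_FLOOR = 1e-10
_ENUM_LIMIT = 2 ** 20  # largest C^p for which exact enumeration is allowed


class NumericalGuardError(ArithmeticError):
    pass


class CapacityError(ValueError):
    pass


class ConvergenceFailureError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# shared helpers


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    return (labels[:, None] == np.arange(k)).astype(float)


def _log_theta(params: Parameters, spec: ModelSpec) -> np.ndarray:
    """(row groups) x (col groups) x q tensor of log cell probabilities."""
    return log_cell_probability_grid(params.mu, linear_predictor_grid(params, spec))


def _safe_log(v: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(v, _LOG_FLOOR))


class _Workspace:
    """Per-dataset contraction caches (one-hot layouts reused across EM steps)."""

    def __init__(self, data: OrdinalMatrix):
        self.data = data
        Yoh = data.one_hot()  # (n, p, q)
        n, p, q = Yoh.shape
        self.Yk = np.ascontiguousarray(Yoh.transpose(2, 0, 1))  # (q, n, p)
        self.Yrow = Yoh.reshape(n, p * q)  # rows against (j, k) blocks
        self.Ycol = np.ascontiguousarray(Yoh.transpose(1, 0, 2)).reshape(p, n * q)

    def weights(self, Z: np.ndarray, X: np.ndarray) -> np.ndarray:
        """W[r, c, k] = sum_ij Z_ir X_jc I(y_ij = k)."""
        q = self.Yk.shape[0]
        W = np.empty((Z.shape[1], X.shape[1], q))
        ZT = np.ascontiguousarray(Z.T)
        for k in range(q):
            W[:, :, k] = (ZT @ self.Yk[k]) @ X
        return W

    def row_scores(self, A: np.ndarray) -> np.ndarray:
        """U[i, r] = sum_jk Yoh[i, j, k] A[j, k, r] for a (p, q, r) score tensor."""
        return self.Yrow @ A.reshape(-1, A.shape[2])

    def col_scores(self, B: np.ndarray) -> np.ndarray:
        """V[j, c] = sum_ik Yoh[i, j, k] B[i, k, c] for an (n, q, c) score tensor."""
        return self.Ycol @ B.reshape(-1, B.shape[2])


def _memberships(data: OrdinalMatrix, spec: ModelSpec, post: Posteriors | None) -> tuple[np.ndarray, np.ndarray]:
    """Effective (n x a) and (p x b) membership-probability matrices.

    Non-latent modes get their known hard memberships; latent modes take the
    posteriors (which must then be present).
    """
    rg = spec.fixed_row_groups(data.n)
    cg = spec.fixed_col_groups(data.p)
    if rg is not None:
        Z = _one_hot(rg, spec.n_row_groups(data.n))
    else:
        if post is None or post.zhat is None:
            raise InvalidSpecError("row posteriors required for a mixed row mode")
        Z = post.zhat
    if cg is not None:
        X = _one_hot(cg, spec.n_col_groups(data.p))
    else:
        if post is None or post.xhat is None:
            raise InvalidSpecError("column posteriors required for a mixed column mode")
        X = post.xhat
    return Z, X


def _entropy(m: np.ndarray | None) -> float:
    if m is None:
        return 0.0
    mm = np.clip(m, _LOG_FLOOR, 1.0)
    return float(-(m * np.log(mm)).sum())


# ---------------------------------------------------------------------------
# incomplete-data log-likelihoods


def _plain_loglik(data: OrdinalMatrix, params: Parameters, spec: ModelSpec) -> float:
    logth = _log_theta(params, spec)
    rg = spec.fixed_row_groups(data.n)
    cg = spec.fixed_col_groups(data.p)
    cell = logth[rg[:, None], cg[None, :], data.values - 1]
    val = float(cell.sum())
    if not np.isfinite(val):
        raise NumericalGuardError("zero-probability cell in the classified likelihood")
    return val


def _row_score(data: OrdinalMatrix, logth: np.ndarray, cg: np.ndarray) -> np.ndarray:
    """S[i, r] = sum_j log theta_{r, c(j), y_ij} for known column groups."""
    T = logth[:, cg, :]  # (a, p, q)
    idx = data.values - 1  # (n, p)
    return T[:, np.arange(data.p)[None, :], idx].sum(axis=2).T  # (n, a)


def incomplete_loglik_row_mixture(data: OrdinalMatrix, params: Parameters, spec: ModelSpec) -> float:
    """``l = sum_i log sum_r pi_r prod_j theta_{r, c(j), y_ij}`` (columns not latent)."""
    if not spec.rows_mixed or spec.cols_mixed:
        raise InvalidSpecError("row-mixture likelihood needs latent rows and non-latent columns")
    logth = _log_theta(params, spec)
    S = _row_score(data, logth, spec.fixed_col_groups(data.p))
    per_row = logsumexp(_safe_log(params.pi)[None, :] + S, axis=1)
    val = float(per_row.sum())
    if not np.isfinite(val):
        raise NumericalGuardError("zero probability under every row component")
    return val


def incomplete_loglik_col_mixture(data: OrdinalMatrix, params: Parameters, spec: ModelSpec) -> float:
    """Mirror image of :func:`incomplete_loglik_row_mixture` for latent columns."""
    if not spec.cols_mixed or spec.rows_mixed:
        raise InvalidSpecError("column-mixture likelihood needs latent columns and non-latent rows")
    logth = _log_theta(params, spec)
    rg = spec.fixed_row_groups(data.n)
    T = logth[rg, :, :]  # (n, b, q)
    idx = data.values - 1
    # advanced indexing yields (n, p, b); summing over rows i gives S[j, c]
    S = T[np.arange(data.n)[:, None], :, idx].sum(axis=0)
    per_col = logsumexp(_safe_log(params.kappa)[None, :] + S, axis=1)
    val = float(per_col.sum())
    if not np.isfinite(val):
        raise NumericalGuardError("zero probability under every column component")
    return val


def _all_assignments(p: int, C: int) -> np.ndarray:
    """All ``C^p`` column assignments as a ``(C^p, p)`` integer array."""
    codes = np.arange(C ** p)
    powers = C ** np.arange(p)
    return (codes[:, None] // powers[None, :]) % C


def _half_scores(E: np.ndarray, A: np.ndarray) -> np.ndarray:
    """S[m, i, r] = sum_j E[j, A[m, j], i, r] for a block of columns."""
    C = E.shape[1]
    Aoh = _one_hot(A.ravel(), C).reshape(A.shape + (C,))
    return np.tensordot(Aoh, E, axes=([1, 2], [0, 1]))


def _exact_bicluster_loglik(data: OrdinalMatrix, params: Parameters, spec: ModelSpec) -> float:
    """Sum over all ``C^p`` column assignments of the row-mixture likelihood.

    The assignment space is split over two column blocks (meet in the
    middle): partial row scores are precomputed per block and combined, so
    the dominant cost is one ``C^p x n`` log-sum-exp rather than a
    ``C^p x n x p`` contraction.
    """
    C, n, p = spec.C, data.n, data.p
    if C ** p > _ENUM_LIMIT:
        raise CapacityError(f"C^p = {C}^{data.p} exceeds the enumeration guard {_ENUM_LIMIT}")
    logth = _log_theta(params, spec)  # (R, C, q)
    idx = data.values - 1
    # E[j, c, i, r] = log theta_{r, c, y_ij}
    E = np.ascontiguousarray(np.transpose(logth[:, :, idx], (3, 1, 2, 0)))
    R = logth.shape[0]
    logpi = _safe_log(params.pi)
    logkappa = _safe_log(params.kappa)

    # block sizes: keep the second block's enumeration small
    p2 = max(1, min(p - 1, int(np.log(64) / np.log(C)))) if p > 1 else 0
    p1 = p - p2
    A1 = _all_assignments(p1, C)
    S1 = _half_scores(E[:p1], A1) + logpi[None, None, :]  # (M1, n, R)
    k1 = logkappa[A1].sum(axis=1)
    if p2 == 0:
        row_term = logsumexp(S1, axis=2).sum(axis=1)
        val = float(logsumexp(k1 + row_term))
    else:
        A2 = _all_assignments(p2, C)
        S2 = _half_scores(E[p1:], A2)  # (M2, n, R)
        k2 = logkappa[A2].sum(axis=1)
        M2 = S2.shape[0]
        chunk = max(1, 2_000_000 // max(1, M2 * n * R))
        parts = []
        for lo in range(0, S1.shape[0], chunk):
            T = S1[lo : lo + chunk, None, :, :] + S2[None, :, :, :]  # (ch, M2, n, R)
            m = T.max(axis=3)
            row = m + np.log(np.exp(T - m[..., None]).sum(axis=3))  # (ch, M2, n)
            parts.append(k1[lo : lo + chunk, None] + k2[None, :] + row.sum(axis=2))
        val = float(logsumexp(np.concatenate([b.ravel() for b in parts])))
    if not np.isfinite(val):
        raise NumericalGuardError("zero probability under every partition")
    return val


def incomplete_loglik_bicluster(
    data: OrdinalMatrix,
    params: Parameters,
    spec: ModelSpec,
    method: Literal["auto", "exact", "bound"] = "auto",
    posteriors: Posteriors | None = None,
) -> tuple[float, str]:
    """Incomplete-data log-likelihood for a two-mode (bi-)clustering model.

    ``exact`` enumerates all column assignments (guarded by ``C^p <= 2^20``);
    ``bound`` returns the variational free energy ``l_c + H(zhat) + H(xhat)``
    at the supplied posteriors, a lower bound on the exact value; ``auto``
    picks ``exact`` when the enumeration is feasible, else ``bound``.
    """
    if not (spec.rows_mixed and spec.cols_mixed):
        raise InvalidSpecError("bicluster likelihood needs both modes latent")
    if method == "auto":
        method = "exact" if spec.C ** data.p <= _ENUM_LIMIT else "bound"
    if method == "exact":
        return _exact_bicluster_loglik(data, params, spec), "exact"
    if method == "bound":
        if posteriors is None:
            posteriors = e_step(data, params, spec)
        lc = complete_loglik(data, params, spec, posteriors)
        return lc + _entropy(posteriors.zhat) + _entropy(posteriors.xhat), "variational_bound"
    raise ValueError(f"unknown method {method!r}")


def incomplete_loglik(
    data: OrdinalMatrix,
    params: Parameters,
    spec: ModelSpec,
    method: Literal["auto", "exact", "bound"] = "auto",
    posteriors: Posteriors | None = None,
) -> tuple[float, str]:
    """Dispatch to the appropriate marginal likelihood for the spec's structure."""
    if spec.rows_mixed and spec.cols_mixed:
        return incomplete_loglik_bicluster(data, params, spec, method, posteriors)
    if spec.rows_mixed:
        return incomplete_loglik_row_mixture(data, params, spec), "exact"
    if spec.cols_mixed:
        return incomplete_loglik_col_mixture(data, params, spec), "exact"
    return _plain_loglik(data, params, spec), "exact"


# ---------------------------------------------------------------------------
# complete-data log-likelihood


def complete_loglik(
    data: OrdinalMatrix, params: Parameters, spec: ModelSpec, posteriors: Posteriors | None
) -> float:
    """Expected complete-data log-likelihood ``l_c``.

    ``l_c = sum_ir zhat_ir log pi_r + sum_jc xhat_jc log kappa_c
    + sum_ijrc zhat_ir xhat_jc log theta_{rc, y_ij}``; the joint expectation
    ``E[Z_ir X_jc]`` is factorised as ``zhat_ir xhat_jc`` (mean field).
    Terms for non-latent modes are dropped.
    """
    bad = validate_posteriors(posteriors or Posteriors(), spec)
    if bad:
        raise InvalidSpecError("; ".join(bad))
    Z, X = _memberships(data, spec, posteriors)
    logth = np.maximum(_log_theta(params, spec), -745.0)  # floor keeps 0 * (-inf) out
    W = _Workspace(data).weights(Z, X)
    val = float((W * logth).sum())
    if spec.rows_mixed:
        val += float(Z.sum(axis=0) @ _safe_log(params.pi))
    if spec.cols_mixed:
        val += float(X.sum(axis=0) @ _safe_log(params.kappa))
    return val


# ---------------------------------------------------------------------------
# E-step


def _softmax_rows(logw: np.ndarray) -> np.ndarray:
    logw = logw - logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def _estep_two_mode(
    ws: _Workspace,
    params: Parameters,
    spec: ModelSpec,
    posteriors: Posteriors | None,
    max_cycles: int,
    tol: float,
) -> Posteriors:
    logth = _log_theta(params, spec)  # (R, C, q)
    p, C = ws.data.p, spec.C
    if posteriors is None or posteriors.xhat is None:
        xhat = np.full((p, C), 1.0 / C)
    else:
        xhat = posteriors.xhat
    zhat = None if posteriors is None else posteriors.zhat
    logpi = _safe_log(params.pi)
    logkappa = _safe_log(params.kappa)
    for _ in range(max_cycles):
        # A[j, k, r] = sum_c xhat_jc log theta_{rck}
        A = np.tensordot(xhat, logth, axes=([1], [1])).transpose(0, 2, 1)
        new_z = _softmax_rows(logpi[None, :] + ws.row_scores(A))
        # B[i, k, c] = sum_r zhat_ir log theta_{rck}
        B = np.tensordot(new_z, logth, axes=([1], [0])).transpose(0, 2, 1)
        new_x = _softmax_rows(logkappa[None, :] + ws.col_scores(B))
        dz = np.inf if zhat is None else np.abs(new_z - zhat).max()
        dx = np.abs(new_x - xhat).max()
        zhat, xhat = new_z, new_x
        if max(dz, dx) < tol:
            break
    return Posteriors(zhat=zhat, xhat=xhat)


def e_step(
    data: OrdinalMatrix,
    params: Parameters,
    spec: ModelSpec,
    posteriors: Posteriors | None = None,
    max_cycles: int = 5,
    tol: float = 1e-6,
    _workspace: _Workspace | None = None,
) -> Posteriors:
    """Posterior membership probabilities at the current parameters.

    One-mode models get the exact posterior in a single pass.  Two-mode
    models alternate the mean-field updates of ``zhat`` and ``xhat`` until
    the largest membership change falls below ``tol`` or ``max_cycles``
    inner cycles have run.  All normalisations happen in log space.
    """
    if not spec.rows_mixed and not spec.cols_mixed:
        return Posteriors()
    if spec.rows_mixed and spec.cols_mixed:
        ws = _workspace if _workspace is not None else _Workspace(data)
        return _estep_two_mode(ws, params, spec, posteriors, max_cycles, tol)
    logth = _log_theta(params, spec)
    if spec.rows_mixed:
        S = _row_score(data, logth, spec.fixed_col_groups(data.p))
        return Posteriors(zhat=_softmax_rows(_safe_log(params.pi)[None, :] + S))
    rg = spec.fixed_row_groups(data.n)
    T = logth[rg, :, :]  # (n, b, q)
    S = T[np.arange(data.n)[:, None], :, data.values - 1].sum(axis=0)  # (p, b)
    return Posteriors(xhat=_softmax_rows(_safe_log(params.kappa)[None, :] + S))


# ---------------------------------------------------------------------------
# M-step


def _empirical_cutpoints(data: OrdinalMatrix) -> np.ndarray:
    """Logits of the pooled empirical cumulative proportions (the null-model MLE)."""
    N = data.values.size
    counts = np.bincount(data.values.ravel(), minlength=data.q + 1)[1:]
    cum = np.cumsum(counts)[:-1] / N
    cum = np.clip(cum, 1.0 / (N + 1), N / (N + 1.0))
    logits = np.log(cum / (1 - cum))
    # enforce strict increase when a category is empty
    for k in range(1, logits.size):
        if logits[k] <= logits[k - 1]:
            logits[k] = logits[k - 1] + 1e-6
    return logits


def _cold_start(data: OrdinalMatrix, spec: ModelSpec) -> Parameters:
    a = spec.n_row_groups(data.n)
    b = spec.n_col_groups(data.p)
    return Parameters(
        mu=_empirical_cutpoints(data),
        alpha=np.zeros(a),
        beta=np.zeros(b),
        gamma=np.zeros((a, b)) if spec.interaction else None,
        pi=np.full(spec.R, 1.0 / spec.R) if spec.rows_mixed else None,
        kappa=np.full(spec.C, 1.0 / spec.C) if spec.cols_mixed else None,
    )


def _pack(params: Parameters, spec: ModelSpec) -> np.ndarray:
    mu = params.mu
    t = [np.array([mu[0]])]
    if mu.size > 1:
        t.append(np.log(np.diff(mu)))
    t.append(params.alpha[1:])
    t.append(params.beta[1:])
    if spec.interaction:
        t.append(params.gamma[1:, 1:].ravel())
    return np.concatenate(t)


def _unpack(t: np.ndarray, spec: ModelSpec, q: int, a: int, b: int):
    pos = q - 1
    mu = np.empty(q - 1)
    mu[0] = t[0]
    if q > 2:
        mu[1:] = t[0] + np.cumsum(np.exp(t[1 : q - 1]))
    alpha = np.concatenate([[0.0], t[pos : pos + a - 1]])
    pos += a - 1
    beta = np.concatenate([[0.0], t[pos : pos + b - 1]])
    pos += b - 1
    gamma = None
    if spec.interaction:
        G = t[pos : pos + (a - 1) * (b - 1)].reshape(a - 1, b - 1)
        gamma = np.empty((a, b))
        gamma[1:, 1:] = G
        gamma[1:, 0] = -G.sum(axis=1)
        gamma[0, 1:] = -G.sum(axis=0)
        gamma[0, 0] = G.sum()
    return mu, alpha, beta, gamma


def _weighted_negloglik(t, W, spec, q, a, b):
    """Negative weighted log-likelihood -sum_rck W_rck log theta_rck and its gradient."""
    mu, alpha, beta, gamma = _unpack(t, spec, q, a, b)
    eta = alpha[:, None] + beta[None, :]
    if gamma is not None:
        eta = eta + gamma
    arg = mu[None, None, :] - eta[:, :, None]  # (a, b, q-1)
    logth = log_cell_probability_grid(mu, eta)
    f = -float((W * np.maximum(logth, -745.0)).sum())

    g = expit(arg)
    theta = np.clip(np.exp(logth), 1e-12, None)
    ratio = W / theta  # (a, b, q)
    s = g * (1.0 - g) * (ratio[:, :, : q - 1] - ratio[:, :, 1:])  # (a, b, q-1)
    dmu = s.sum(axis=(0, 1))  # (q-1,)
    deta = -s.sum(axis=2)  # (a, b)

    grad = np.empty_like(t)
    grad[0] = dmu.sum()
    if q > 2:
        # mu_k = mu_1 + cumsum(exp(u)); d/du_l = exp(u_l) * sum_{k >= l} dmu_k
        tail = np.cumsum(dmu[::-1])[::-1][1:]
        grad[1 : q - 1] = np.exp(t[1 : q - 1]) * tail
    pos = q - 1
    grad[pos : pos + a - 1] = deta.sum(axis=1)[1:]
    pos += a - 1
    grad[pos : pos + b - 1] = deta.sum(axis=0)[1:]
    pos += b - 1
    if spec.interaction:
        D = deta
        grad[pos:] = (D[1:, 1:] - D[1:, :1] - D[:1, 1:] + D[0, 0]).ravel()
    return f, -grad


def _maximise_weighted(W, spec, q, a, b, t0, max_opt_iter, t_retry=None):
    """Quasi-Newton ascent of the weighted log-likelihood; never worse than t0.

    A non-finite outcome triggers one retry from the fresh transform start
    ``t_retry`` before a convergence failure is raised with diagnostics.
    """
    res = minimize(
        _weighted_negloglik,
        t0,
        args=(W, spec, q, a, b),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_opt_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not np.isfinite(res.fun) and t_retry is not None:
        res = minimize(
            _weighted_negloglik,
            t_retry,
            args=(W, spec, q, a, b),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-7},
        )
    if not np.isfinite(res.fun):
        raise ConvergenceFailureError(
            "M-step optimiser failed", {"status": res.status, "message": res.message}
        )
    f0, _ = _weighted_negloglik(t0, W, spec, q, a, b)
    if res.fun <= f0 + 1e-8 or not np.isfinite(f0):
        return res.x, -float(res.fun)
    return t0, -float(f0)


def _mstep_core(ws, spec, posteriors, params_init, max_opt_iter):
    """Shared M-step: returns (params, wlog) with wlog = max sum W log theta."""
    data = ws.data
    q = data.q
    a = spec.n_row_groups(data.n)
    b = spec.n_col_groups(data.p)
    Z, X = _memberships(data, spec, posteriors)
    W = ws.weights(Z, X)
    start = params_init if params_init is not None else _cold_start(data, spec)
    t_best, wlog = _maximise_weighted(
        W, spec, q, a, b, _pack(start, spec), max_opt_iter,
        t_retry=_pack(_cold_start(data, spec), spec),
    )
    mu, alpha, beta, gamma = _unpack(t_best, spec, q, a, b)
    params = Parameters(
        mu=mu, alpha=alpha, beta=beta, gamma=gamma,
        pi=Z.mean(axis=0) if spec.rows_mixed else None,
        kappa=X.mean(axis=0) if spec.cols_mixed else None,
    )
    return params, wlog, Z, X


def m_step(
    data: OrdinalMatrix,
    spec: ModelSpec,
    posteriors: Posteriors | None,
    params_init: Parameters | None = None,
    max_opt_iter: int = 200,
) -> Parameters:
    """Maximise ``l_c`` over cutpoints and effects; closed-form mixing updates.

    ``pi_r = mean_i zhat_ir`` and ``kappa_c = mean_j xhat_jc``; the remaining
    parameters are optimised by L-BFGS with analytic gradients on the
    transformed (unconstrained) scale, warm-started at ``params_init``.
    """
    bad = validate_posteriors(posteriors or Posteriors(), spec)
    if bad:
        raise InvalidSpecError("; ".join(bad))
    params, _, _, _ = _mstep_core(_Workspace(data), spec, posteriors, params_init, max_opt_iter)
    return params


# ---------------------------------------------------------------------------
# full EM with restarts


@dataclass
class FitResult:
    """Outcome of an EM fit: parameters, fuzzy memberships and diagnostics."""

    spec: ModelSpec
    params: Parameters
    posteriors: Posteriors
    loglik: float
    loglik_flag: str  # "exact" | "variational_bound"
    loglik_complete: float
    entropy: float
    n_iter: int
    converged: bool
    seed: int
    nu: int
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "row_structure": self.spec.row_structure,
                "col_structure": self.spec.col_structure,
                "R": self.spec.R,
                "C": self.spec.C,
                "interaction": self.spec.interaction,
            },
            "params": self.params.to_dict(),
            "zhat": None if self.posteriors.zhat is None else self.posteriors.zhat.tolist(),
            "xhat": None if self.posteriors.xhat is None else self.posteriors.xhat.tolist(),
            "loglik": self.loglik,
            "loglik_flag": self.loglik_flag,
            "loglik_complete": self.loglik_complete,
            "entropy": self.entropy,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
            "nu": self.nu,
            "trace": list(self.trace),
        }


def _objective(data, params, spec, post) -> tuple[float, str]:
    """EM surrogate tracked across iterations: exact l when available, else the bound."""
    if spec.rows_mixed and spec.cols_mixed:
        return incomplete_loglik_bicluster(data, params, spec, "bound", post)
    return incomplete_loglik(data, params, spec)


def _fast_objective(ws, params, spec, post, wlog, Z, X) -> float:
    """Tracked objective reusing the M-step's weighted log-likelihood value.

    For two-mode models this is the free energy
    ``F = wlog + sum_r n_r log pi_r + sum_c p_c log kappa_c + H(z) + H(x)``;
    for one-mode models the exact marginal likelihood is recomputed.
    """
    if spec.rows_mixed and spec.cols_mixed:
        val = wlog
        val += float(Z.sum(axis=0) @ _safe_log(params.pi))
        val += float(X.sum(axis=0) @ _safe_log(params.kappa))
        return val + _entropy(post.zhat) + _entropy(post.xhat)
    if spec.rows_mixed:
        return incomplete_loglik_row_mixture(ws.data, params, spec)
    return incomplete_loglik_col_mixture(ws.data, params, spec)


def _canonicalize(params: Parameters, spec: ModelSpec, post: Posteriors) -> tuple[Parameters, Posteriors]:
    """Sort latent clusters by decreasing effect and re-impose the baselines.

    Sorting resolves label switching for reporting; re-baselining shifts the
    cutpoints so that the cell probabilities are unchanged.
    """
    params = params.copy()
    post = post.copy()
    if spec.rows_mixed:
        order = np.argsort(-params.alpha, kind="stable")
        params.alpha = params.alpha[order]
        params.pi = params.pi[order]
        if params.gamma is not None:
            params.gamma = params.gamma[order, :]
        post.zhat = post.zhat[:, order]
        shift = params.alpha[0]
        params.alpha = params.alpha - shift
        params.mu = params.mu - shift
    if spec.cols_mixed:
        order = np.argsort(-params.beta, kind="stable")
        params.beta = params.beta[order]
        params.kappa = params.kappa[order]
        if params.gamma is not None:
            params.gamma = params.gamma[:, order]
        post.xhat = post.xhat[:, order]
        shift = params.beta[0]
        params.beta = params.beta - shift
        params.mu = params.mu - shift
    return params, post


def _init_posteriors(data: OrdinalMatrix, spec: ModelSpec, rng: np.random.Generator) -> Posteriors:
    """Random restart: symmetric Dirichlet(1.5) memberships per row/column."""
    zhat = rng.dirichlet(np.full(spec.R, 1.5), size=data.n) if spec.rows_mixed else None
    xhat = rng.dirichlet(np.full(spec.C, 1.5), size=data.p) if spec.cols_mixed else None
    return Posteriors(zhat=zhat, xhat=xhat)


def fit(
    data: OrdinalMatrix,
    spec: ModelSpec,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    canonical_order: bool = True,
    inner_opt_iter: int = 25,
) -> FitResult:
    """Fit one model by EM with multiple random restarts.

    Each restart draws random fuzzy memberships, runs one M-step, then
    alternates E and M steps until the relative change of the tracked
    objective (exact ``l`` for one-mode models, the variational free energy
    for two-mode models) drops below ``tol`` or ``max_iter`` is reached.
    The restart with the highest final objective wins.  Results are
    reproducible bit for bit given the same arguments.
    """
    spec.check_dimensions(data.n, data.p)
    nu = count_parameters(spec, data.n, data.p, data.q)

    if not spec.rows_mixed and not spec.cols_mixed:
        # memberships are known: a single M-step maximises the exact likelihood
        params = m_step(data, spec, Posteriors(), None)
        ll = _plain_loglik(data, params, spec)
        return FitResult(
            spec=spec, params=params, posteriors=Posteriors(), loglik=ll,
            loglik_flag="exact", loglik_complete=ll, entropy=0.0, n_iter=1,
            converged=True, seed=seed, nu=nu, trace=[ll],
        )

    ws = _Workspace(data)
    best = None
    failures: list[str] = []
    for s_idx in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(s_idx)]))
        try:
            post = _init_posteriors(data, spec, rng)
            params, wlog, Z, X = _mstep_core(ws, spec, post, None, inner_opt_iter)
            obj = _fast_objective(ws, params, spec, post, wlog, Z, X)
            trace = [obj]
            converged = False
            for _ in range(max_iter):
                post = e_step(data, params, spec, post, _workspace=ws)
                params, wlog, Z, X = _mstep_core(ws, spec, post, params, inner_opt_iter)
                new_obj = _fast_objective(ws, params, spec, post, wlog, Z, X)
                trace.append(new_obj)
                if abs(new_obj - obj) <= tol * (abs(obj) + 1e-12):
                    obj = new_obj
                    converged = True
                    break
                obj = new_obj
        except (ConvergenceFailureError, NumericalGuardError) as exc:  # pragma: no cover
            failures.append(f"start {s_idx}: {exc}")
            continue
        log.debug(
            "restart %d/%d: objective %.6f after %d iterations (converged=%s)",
            s_idx + 1, n_starts, obj, len(trace) - 1, converged,
        )
        if best is None or obj > best[0]:
            best = (obj, params, post, trace, converged, s_idx)
    if best is None:
        raise ConvergenceFailureError("all EM restarts failed", {"failures": failures})

    obj, params, post, trace, converged, s_idx = best
    # polish: full M-step at the winning solution, then refresh the posteriors
    # so the reported entropy identity EN = l - l_c holds exactly
    post = e_step(data, params, spec, post, _workspace=ws)
    params, _, _, _ = _mstep_core(ws, spec, post, params, 200)
    post = e_step(data, params, spec, post, _workspace=ws)
    if canonical_order:
        params, post = _canonicalize(params, spec, post)
    # report the exact marginal likelihood whenever enumeration is feasible;
    # otherwise the variational bound, with the flag recording which one
    ll, flag = incomplete_loglik(data, params, spec, "auto", post)
    lc = complete_loglik(data, params, spec, post)
    return FitResult(
        spec=spec, params=params, posteriors=post, loglik=ll, loglik_flag=flag,
        loglik_complete=lc, entropy=ll - lc, n_iter=len(trace) - 1,
        converged=converged, seed=s_idx, nu=nu, trace=trace,
    )
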