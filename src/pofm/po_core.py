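"""Proportional-odds model family for two-mode ordinal data.

An ``n x p`` matrix of ordered categorical responses (codes ``1..q``) is
modelled through cumulative logits

    logit P(Y_ij <= k) = mu_k - eta_ij,    1 <= k < q,

where ``mu_1 < ... < mu_{q-1}`` are cutpoints on the latent logistic scale
and ``eta_ij`` collects row and column effects.  Rows and/or columns may be
homogeneous (a single group), fully heterogeneous (each its own group), or
drawn from a finite mixture of ``R`` (resp. ``C``) latent clusters with
mixing proportions ``pi`` (resp. ``kappa``).  Clustered modes may also
interact through a doubly-centred term ``gamma_rc``.

This module defines the model family itself: the data container, the model
specification, the parameter container with its identifiability constraints
(``alpha_1 = beta_1 = 0``, gamma rows/columns sum to zero), cell
probabilities, linear predictors, and parameter counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "SINGLE",
    "CLUSTERED",
    "SATURATED",
    "OrdinalMatrix",
    "ModelSpec",
    "Parameters",
    "Posteriors",
    "cell_probabilities",
    "log_cell_probability_grid",
    "linear_predictor",
    "linear_predictor_grid",
    "count_parameters",
    "validate",
]

SINGLE = "single"
CLUSTERED = "clustered"
SATURATED = "saturated"
_STRUCTURES = (SINGLE, CLUSTERED, SATURATED)


class InvalidSpecError(ValueError):
    """A model specification is internally inconsistent or does not fit the data."""


class ConstraintViolationError(ValueError):
    """A parameter value breaks a model constraint (e.g. non-monotone cutpoints)."""


# ---------------------------------------------------------------------------
# data container


@dataclass(frozen=True)
class OrdinalMatrix:
    """An ``n x p`` grid of ordinal responses coded ``1..q``.

    ``q`` is declared by the caller, never inferred from the data: a column
    on a 5-point scale keeps ``q = 5`` even if nobody ticked category 5.
    """

    values: np.ndarray
    q: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.size == 0:
            raise InvalidSpecError("response matrix must be 2-D and non-empty")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.floor(vals)):
                raise InvalidSpecError("response codes must be integers")
            vals = vals.astype(np.int64)
        if self.q < 2:
            raise InvalidSpecError(f"q must be >= 2, got {self.q}")
        if vals.min() < 1 or vals.max() > self.q:
            raise InvalidSpecError(
                f"response codes must lie in [1, {self.q}]; "
                f"found range [{vals.min()}, {vals.max()}]"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def one_hot(self) -> np.ndarray:
        """Indicator array of shape ``(n, p, q)`` with ``[i, j, k] = I(y_ij = k+1)``."""
        cached = getattr(self, "_one_hot_cache", None)
        if cached is None:
            cached = (self.values[:, :, None] == np.arange(1, self.q + 1)).astype(float)
            object.__setattr__(self, "_one_hot_cache", cached)
        return cached

    @classmethod
    def from_csv(cls, path: str | Path, q: int, *, zero_based: bool = False) -> "OrdinalMatrix":
        """Read a matrix of comma-separated integer codes.

        A single non-numeric header row is tolerated and skipped.  Missing
        values are not permitted (the models assume complete cases).
        """
        path = Path(path)
        with path.open() as fh:
            first = fh.readline()
        skip = 0
        try:
            [float(tok) for tok in first.strip().split(",") if tok != ""]
        except ValueError:
            skip = 1
        vals = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
        if np.isnan(vals).any():
            raise InvalidSpecError(f"{path}: missing values are not permitted")
        vals = vals.astype(np.int64)
        if zero_based:
            vals = vals + 1
        return cls(vals, q)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%d")


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model family to fit.

    ``row_structure`` / ``col_structure`` are one of ``"single"`` (one
    homogeneous group, effect fixed at 0), ``"clustered"`` (finite mixture of
    ``R`` / ``C`` latent groups) or ``"saturated"`` (every row / column its
    own group, membership known).  ``interaction`` adds the doubly-centred
    ``gamma`` term and requires neither mode to be ``"single"``.
    """

    row_structure: str = SINGLE
    col_structure: str = SINGLE
    R: int | None = None
    C: int | None = None
    interaction: bool = False

    def __post_init__(self) -> None:
        for name, s in (("row_structure", self.row_structure), ("col_structure", self.col_structure)):
            if s not in _STRUCTURES:
                raise InvalidSpecError(f"{name} must be one of {_STRUCTURES}, got {s!r}")
        if (self.row_structure == CLUSTERED) != (self.R is not None):
            raise InvalidSpecError("R must be given iff row_structure is 'clustered'")
        if (self.col_structure == CLUSTERED) != (self.C is not None):
            raise InvalidSpecError("C must be given iff col_structure is 'clustered'")
        if self.R is not None and self.R < 1:
            raise InvalidSpecError("R must be >= 1")
        if self.C is not None and self.C < 1:
            raise InvalidSpecError("C must be >= 1")
        if self.interaction and (self.row_structure == SINGLE or self.col_structure == SINGLE):
            raise InvalidSpecError("interaction requires neither mode to be 'single'")
        if self.interaction and self.row_structure == SATURATED and self.col_structure == SATURATED:
            raise InvalidSpecError("saturated-by-saturated interaction is not identifiable")

    # -- derived structure ------------------------------------------------

    @property
    def rows_mixed(self) -> bool:
        """True when row membership is latent (R > 1 finite mixture)."""
        return self.row_structure == CLUSTERED and (self.R or 1) > 1

    @property
    def cols_mixed(self) -> bool:
        return self.col_structure == CLUSTERED and (self.C or 1) > 1

    def n_row_groups(self, n: int) -> int:
        if self.row_structure == SINGLE:
            return 1
        if self.row_structure == SATURATED:
            return n
        return int(self.R)

    def n_col_groups(self, p: int) -> int:
        if self.col_structure == SINGLE:
            return 1
        if self.col_structure == SATURATED:
            return p
        return int(self.C)

    def check_dimensions(self, n: int, p: int) -> None:
        if self.row_structure == CLUSTERED and not (1 <= self.R <= n):
            raise InvalidSpecError(f"need 1 <= R <= n, got R={self.R}, n={n}")
        if self.col_structure == CLUSTERED and not (1 <= self.C <= p):
            raise InvalidSpecError(f"need 1 <= C <= p, got C={self.C}, p={p}")

    def fixed_row_groups(self, n: int) -> np.ndarray | None:
        """Known 0-based row-group labels, or None when membership is latent."""
        if self.row_structure == SINGLE:
            return np.zeros(n, dtype=int)
        if self.row_structure == SATURATED:
            return np.arange(n)
        if (self.R or 1) == 1:
            return np.zeros(n, dtype=int)
        return None

    def fixed_col_groups(self, p: int) -> np.ndarray | None:
        if self.col_structure == SINGLE:
            return np.zeros(p, dtype=int)
        if self.col_structure == SATURATED:
            return np.arange(p)
        if (self.C or 1) == 1:
            return np.zeros(p, dtype=int)
        return None

    def label(self) -> str:
        r = {SINGLE: "1", SATURATED: "n", CLUSTERED: f"R{self.R}"}[self.row_structure]
        c = {SINGLE: "1", SATURATED: "p", CLUSTERED: f"C{self.C}"}[self.col_structure]
        return f"{r}x{c}{'+int' if self.interaction else ''}"


# ---------------------------------------------------------------------------
# parameters


@dataclass
class Parameters:
    """Cutpoints, group effects, interaction and mixing proportions.

    Effects follow the baseline constraints ``alpha[0] = beta[0] = 0``; the
    interaction matrix ``gamma`` is doubly centred (every row and column sums
    to zero); ``pi`` / ``kappa`` live on the simplex and are present only for
    a mixed (latent clustered) mode.
    """

    mu: np.ndarray
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(1))
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))
    gamma: np.ndarray | None = None
    pi: np.ndarray | None = None
    kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)

    @property
    def q(self) -> int:
        return self.mu.size + 1

    def copy(self) -> "Parameters":
        return Parameters(
            mu=self.mu.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
            pi=None if self.pi is None else self.pi.copy(),
            kappa=None if self.kappa is None else self.kappa.copy(),
        )

    def to_dict(self) -> dict:
        out = {"mu": self.mu.tolist(), "alpha": self.alpha.tolist(), "beta": self.beta.tolist()}
        for name in ("gamma", "pi", "kappa"):
            v = getattr(self, name)
            out[name] = None if v is None else np.asarray(v).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        return cls(
            mu=np.asarray(d["mu"], float),
            alpha=np.asarray(d["alpha"], float),
            beta=np.asarray(d["beta"], float),
            gamma=None if d.get("gamma") is None else np.asarray(d["gamma"], float),
            pi=None if d.get("pi") is None else np.asarray(d["pi"], float),
            kappa=None if d.get("kappa") is None else np.asarray(d["kappa"], float),
        )


@dataclass
class Posteriors:
    """Fuzzy membership probabilities for latent-clustered modes.

    ``zhat[i, r]`` is the posterior probability that row ``i`` belongs to row
    cluster ``r``; ``xhat[j, c]`` likewise for columns.  Each is ``None``
    when the corresponding mode has no latent clustering.
    """

    zhat: np.ndarray | None = None
    xhat: np.ndarray | None = None

    def copy(self) -> "Posteriors":
        return Posteriors(
            zhat=None if self.zhat is None else self.zhat.copy(),
            xhat=None if self.xhat is None else self.xhat.copy(),
        )


# ---------------------------------------------------------------------------
# probabilities and predictors


def cell_probabilities(mu: Sequence[float] | np.ndarray, eta: float) -> np.ndarray:
    """Category probabilities ``(theta_1, ..., theta_q)`` under the PO model.

    ``theta_k = F(mu_k - eta) - F(mu_{k-1} - eta)`` with ``F`` the standard
    logistic CDF and ``mu_0 = -inf``, ``mu_q = +inf``.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.size < 1:
        raise InvalidSpecError("need at least one cutpoint (q >= 2)")
    if mu.size > 1 and not np.all(np.diff(mu) > 0):
        raise ConstraintViolationError(f"cutpoints must be strictly increasing, got {mu}")
    if not np.isfinite(eta):
        raise ConstraintViolationError("linear predictor must be finite")
    return np.exp(log_cell_probability_grid(mu, np.array([[eta]]))[0, 0])


def log_cell_probability_grid(mu: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """``log theta`` for every (cell of eta, category): shape ``eta.shape + (q,)``.

    Computed without cancellation: for ``a = mu_k - eta >= b = mu_{k-1} - eta``,
    ``log(F(a) - F(b)) = a + log(1 - e^{b-a}) + log F(-a) + log F(-b)``.
    """
    mu = np.asarray(mu, dtype=float)
    eta = np.asarray(eta, dtype=float)
    q = mu.size + 1
    a = mu.reshape((1,) * eta.ndim + (-1,)) - eta[..., None]  # (..., q-1)
    out = np.empty(eta.shape + (q,))
    out[..., 0] = log_expit(a[..., 0])
    out[..., q - 1] = log_expit(-a[..., q - 2])
    if q > 2:
        hi, lo = a[..., 1:], a[..., :-1]
        with np.errstate(divide="ignore"):
            gap = np.log(-np.expm1(np.minimum(lo - hi, -1e-300)))
        out[..., 1 : q - 1] = hi + gap + log_expit(-hi) + log_expit(-lo)
    return out


def linear_predictor_grid(params: Parameters, spec: ModelSpec) -> np.ndarray:
    """The ``(row groups) x (col groups)`` grid of ``eta_rc = alpha_r + beta_c (+ gamma_rc)``."""
    eta = params.alpha[:, None] + params.beta[None, :]
    if spec.interaction:
        if params.gamma is None:
            raise InvalidSpecError("spec requests an interaction but gamma is absent")
        eta = eta + params.gamma
    elif params.gamma is not None and np.any(params.gamma != 0):
        raise InvalidSpecError("gamma present on an additive spec")
    return eta


def linear_predictor(params: Parameters, spec: ModelSpec, row_group: int, col_group: int) -> float:
    """``eta`` for one (row group, column group) pair; groups are 1-based."""
    grid = linear_predictor_grid(params, spec)
    if not (1 <= row_group <= grid.shape[0] and 1 <= col_group <= grid.shape[1]):
        raise InvalidSpecError(
            f"group indices ({row_group}, {col_group}) outside grid {grid.shape}"
        )
    return float(grid[row_group - 1, col_group - 1])


# ---------------------------------------------------------------------------
# parameter counting


def count_parameters(spec: ModelSpec, n: int, p: int, q: int) -> int:
    """Number of free parameters ``nu``.

    ``(q-1)`` cutpoints, ``a-1`` free row effects and ``b-1`` free column
    effects (``a``, ``b`` the effective group counts), ``R-1`` / ``C-1``
    mixing proportions for mixed modes, and ``(a-1)(b-1)`` free interaction
    cells under the double sum-to-zero constraint.
    """
    spec.check_dimensions(n, p)
    a = spec.n_row_groups(n)
    b = spec.n_col_groups(p)
    nu = (q - 1) + (a - 1) + (b - 1)
    if spec.row_structure == CLUSTERED:
        nu += spec.R - 1
    if spec.col_structure == CLUSTERED:
        nu += spec.C - 1
    if spec.interaction:
        nu += (a - 1) * (b - 1)
    return nu


# ---------------------------------------------------------------------------
# validation


def validate(params: Parameters, spec: ModelSpec, n: int | None = None, p: int | None = None) -> list[str]:
    """Collect constraint violations; an empty list means the parameters are valid."""
    out: list[str] = []
    mu = params.mu
    if mu.size < 1:
        out.append("mu: need at least one cutpoint")
    elif mu.size > 1 and not np.all(np.diff(mu) > 0):
        out.append("mu: cutpoints must be strictly increasing")
    if params.alpha.size and params.alpha[0] != 0:
        out.append("alpha: baseline constraint alpha[1] = 0 violated")
    if params.beta.size and params.beta[0] != 0:
        out.append("beta: baseline constraint beta[1] = 0 violated")
    if spec.interaction:
        g = params.gamma
        if g is None:
            out.append("gamma: required by an interaction spec but absent")
        else:
            if np.abs(g.sum(axis=1)).max() > 1e-10 or np.abs(g.sum(axis=0)).max() > 1e-10:
                out.append("gamma: rows and columns must each sum to zero")
    for name, v, mode in (("pi", params.pi, spec.rows_mixed), ("kappa", params.kappa, spec.cols_mixed)):
        if mode:
            if v is None:
                out.append(f"{name}: required for a mixed mode but absent")
                continue
            if np.any(v < 0):
                out.append(f"{name}: proportions must be non-negative")
            if abs(v.sum() - 1.0) > 1e-12:
                out.append(f"{name}: proportions must sum to 1 (simplex constraint)")
    if n is not None and p is not None:
        a, b = spec.n_row_groups(n), spec.n_col_groups(p)
        if params.alpha.size != a:
            out.append(f"alpha: expected length {a}, got {params.alpha.size}")
        if params.beta.size != b:
            out.append(f"beta: expected length {b}, got {params.beta.size}")
    return out


def validate_posteriors(post: Posteriors, spec: ModelSpec) -> list[str]:
    out: list[str] = []
    for name, m, needed in (("zhat", post.zhat, spec.rows_mixed), ("xhat", post.xhat, spec.cols_mixed)):
        if not needed:
            continue
        if m is None:
            out.append(f"{name}: required for a mixed mode but absent")
            continue
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            out.append(f"{name}: entries must lie in [0, 1]")
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-10:
            out.append(f"{name}: each row must sum to 1")
    return out
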