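"""Negative-binomial duration models for dominance spells (Models G, N, Ng, R, Rg).

The c-th dominance duration of attribute j by panelist i, ``Y[i, j, c]``,
is modeled as negative binomial with mean mu and shape kappa,

    f(y; mu, kappa) = Gamma(y + kappa) / (Gamma(y + 1) Gamma(kappa))
                      * (mu / (mu + kappa))**y * (kappa / (mu + kappa))**kappa,

on support {0, 1, 2, ...}; kappa = 1 gives the geometric distribution and
kappa -> inf the Poisson.  Under negative binomial regression (NBR) the
mean follows a log link in the panelist's covariate vector x_i,

    mu[i, j] = exp(beta[g, 0] + sum_m beta[g, m] * x[i, m]),

with coefficients beta_g and shape kappa_g tied across all attributes of
group g.  The model families compared by AIC are:

====== ==================================================== ===========
family description                                          parameters
====== ==================================================== ===========
G      one geometric for all attributes (a plain Markov      1
       chain in disguise)
N      one negative binomial for all attributes              2
Ng     one negative binomial per attribute group             2G
R      NBR with coefficients shared by all attributes        M + 2
Rg     NBR with per-group coefficients and shapes            (M + 2) G
====== ==================================================== ===========

Observed durations are >= 1 s while the NB support starts at 0; by default
the models describe y - 1 (``support_shift``), which keeps the kappa = 1
case exactly the geometric distribution on {1, 2, ...} implied by a
first-order Markov chain.  Fitting maximizes the exact likelihood over
(beta, log kappa) by L-BFGS-B with analytic gradients and a small
multistart over log kappa; groups are independent blocks for Ng/Rg, so
they are fitted separately (same optimum, better conditioning).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln

from .data import AttributeScheme, CovariateTable, DurationTable

__all__ = [
    "FAMILIES",
    "FitError",
    "EmptyGroupError",
    "ModelSpec",
    "DurationFit",
    "SelectionResult",
    "nb_pmf",
    "nb_logpmf",
    "mean_link",
    "param_count",
    "aic",
    "fit",
    "select_covariates",
]

FAMILIES = ("G", "N", "Ng", "R", "Rg")

KAPPA_CAP = 1e6  # shapes at this bound are flagged as the Poisson limit
_KAPPA_FLOOR = 1e-4
_BETA_BOUND = 30.0


class FitError(RuntimeError):
    """Maximum-likelihood fitting could not be carried out."""


class EmptyGroupError(FitError):
    """A grouped family was requested but a group has no observed durations."""

    def __init__(self, group_name: str):
        self.group_name = group_name
        super().__init__(
            f"attribute group {group_name!r} has no observed durations; "
            "cannot fit a per-group model"
        )


# ---------------------------------------------------------------------------
# distribution primitives


def nb_logpmf(y, mu, kappa):
    """Log NB pmf at ``y`` (support {0, 1, ...}), evaluated stably in log space."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a nonnegative integer")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    eta = np.log(mu)
    logk = np.log(kappa)
    norm = np.logaddexp(eta, logk)  # log(mu + kappa)
    return (
        gammaln(y + kappa)
        - gammaln(y + 1.0)
        - gammaln(kappa)
        + y * (eta - norm)
        + kappa * (logk - norm)
    )


def nb_pmf(y, mu, kappa):
    """NB pmf with mean ``mu`` and shape ``kappa``; kappa=1 is geometric, kappa->inf Poisson."""
    return np.exp(nb_logpmf(y, mu, kappa))


def mean_link(x: Sequence[float], beta: Sequence[float]) -> float:
    """Log-link mean ``exp(beta_0 + sum_m beta_m x_m)``.

    ``beta`` has length M+1 (leading intercept); ``x`` has length M and is
    augmented internally with the constant 1.
    """
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.ndim != 1 or beta.ndim != 1 or beta.size != x.size + 1:
        raise ValueError(
            f"beta must have length M+1 for x of length M (got {beta.size} vs {x.size})"
        )
    return float(np.exp(beta[0] + x @ beta[1:]))


def param_count(family: str, n_covariates: int, n_groups: int) -> int:
    """Free-parameter count of a duration family: G->1, N->2, Ng->2G, R->M+2, Rg->(M+2)G."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if n_covariates < 0 or n_groups < 1:
        raise ValueError("need n_covariates >= 0 and n_groups >= 1")
    M, G = n_covariates, n_groups
    return {"G": 1, "N": 2, "Ng": 2 * G, "R": M + 2, "Rg": (M + 2) * G}[family]


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, ``-2 loglik + 2 n_params`` (lower is better)."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return -2.0 * float(loglik) + 2.0 * int(n_params)


# ---------------------------------------------------------------------------
# model specification and fit result


@dataclass(frozen=True)
class ModelSpec:
    """One duration-model family with its covariate subset and support convention."""

    family: str
    covariates: tuple[str, ...] = ()
    support_shift: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family not in ("R", "Rg") and self.covariates:
            raise ValueError(f"family {self.family} does not take covariates")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def uses_covariates(self) -> bool:
        return self.family in ("R", "Rg")

    @property
    def grouped(self) -> bool:
        return self.family in ("Ng", "Rg")

    def n_params(self, n_groups: int) -> int:
        return param_count(self.family, len(self.covariates), n_groups)


@dataclass
class DurationFit:
    """Maximum-likelihood fit of one duration family.

    ``beta`` is (n_blocks, M+1) and ``kappa`` (n_blocks,), where n_blocks is
    the number of attribute groups for the grouped families and 1 otherwise
    (one shared parameter set).  ``boundary`` flags blocks whose shape hit
    the upper cap (Poisson limit).
    """

    spec: ModelSpec
    scheme: AttributeScheme
    beta: np.ndarray
    kappa: np.ndarray
    loglik: float
    n_params: int
    aic: float
    converged: bool
    boundary: np.ndarray
    n_obs: int
    covariate_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_blocks(self) -> int:
        return self.beta.shape[0]

    def block_of_group(self, group: int) -> int:
        return group if self.spec.grouped else 0

    def beta_for_group(self, group: int) -> np.ndarray:
        return self.beta[self.block_of_group(group)]

    def kappa_for_group(self, group: int) -> float:
        return float(self.kappa[self.block_of_group(group)])

    def mean_for(self, group: int, x: Sequence[float] | None = None) -> float:
        """Model mean of the (shifted) duration for a group / covariate profile."""
        beta = self.beta_for_group(group)
        if self.spec.uses_covariates:
            if x is None:
                raise ValueError("covariate profile required for families R/Rg")
            return mean_link(np.asarray(x, dtype=float), beta)
        return float(np.exp(beta[0]))

    def log_pmf(self, duration: int, group: int, x: Sequence[float] | None = None) -> float:
        """Log probability of an observed duration (>= 1 s) for one spell."""
        y = duration - 1 if self.spec.support_shift else duration
        if y < 0:
            raise ValueError("duration must be >= 1 second")
        mu = self.mean_for(group, x)
        return float(nb_logpmf(y, mu, self.kappa_for_group(group)))

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: one row per attribute group, columns Intercept, covariates, kappa."""
        rows = []
        for g in range(self.scheme.n_groups):
            b = self.beta_for_group(g)
            row = {"group": self.scheme.group_names[g], "Intercept": b[0]}
            for m, name in enumerate(self.covariate_names, start=1):
                row[name] = b[m]
            row["kappa"] = self.kappa_for_group(g)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood and optimizer


def _nll_grad(params: np.ndarray, y: np.ndarray, X: np.ndarray, fixed_logk: float | None):
    """Negative NB log-likelihood and gradient over (beta, [log kappa])."""
    if fixed_logk is None:
        beta, logk = params[:-1], params[-1]
    else:
        beta, logk = params, fixed_logk
    eta = X @ beta
    k = np.exp(logk)
    norm = np.logaddexp(eta, logk)  # log(mu + kappa)
    ll = (
        gammaln(y + k)
        - gammaln(y + 1.0)
        - gammaln(k)
        + y * (eta - norm)
        + k * (logk - norm)
    )
    # d ll / d eta = y - (y + k) * mu/(mu+k)
    sig = expit(eta - logk)  # mu / (mu + kappa)
    resid = y - (y + k) * sig
    gbeta = X.T @ resid
    if fixed_logk is None:
        # d ll / d log kappa
        glogk = k * (digamma(y + k) - digamma(k) + logk + 1.0 - norm) - (y + k) * (1.0 - sig)
        grad = np.append(gbeta, glogk.sum())
    else:
        grad = gbeta
    return -ll.sum(), -grad


def _converged(res) -> bool:
    """L-BFGS-B sometimes ends a line search abnormally at the optimum; a
    vanishing projected gradient counts as convergence."""
    if res.success:
        return True
    return float(np.abs(res.jac).max()) <= 1e-5 * (1.0 + abs(float(res.fun)))


def _fit_block(
    y: np.ndarray, X: np.ndarray, fix_kappa: float | None = None
) -> tuple[np.ndarray, float, float, bool, bool]:
    """Fit one independent parameter block; returns (beta, kappa, loglik, converged, boundary)."""
    n, p = X.shape
    beta0 = np.zeros(p)
    beta0[0] = np.log(y.mean() + 0.1)
    bounds_beta = [(-_BETA_BOUND, _BETA_BOUND)] * p
    if fix_kappa is not None:
        res = minimize(
            _nll_grad,
            beta0,
            args=(y, X, float(np.log(fix_kappa))),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds_beta,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        return res.x.copy(), float(fix_kappa), -float(res.fun), _converged(res), False

    best = None
    for logk0 in (-1.0, 0.0, 2.0):
        start = np.append(beta0, logk0)
        res = minimize(
            _nll_grad,
            start,
            args=(y, X, None),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds_beta + [(np.log(_KAPPA_FLOOR), np.log(KAPPA_CAP))],
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa = float(np.exp(best.x[-1]))
    boundary = kappa >= 0.99 * KAPPA_CAP
    return best.x[:-1].copy(), kappa, -float(best.fun), _converged(best), boundary


def _design(
    durations: DurationTable,
    spec: ModelSpec,
    covariates: CovariateTable | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observation vectors (y_shifted, X, group) for the fit, dropping panelists
    absent from the covariate table for covariate families."""
    frame = durations.frame
    if spec.uses_covariates:
        if covariates is None:
            raise FitError(f"family {spec.family} requires a covariate table")
        missing = [v for v in spec.covariates if v not in covariates.variables]
        if missing:
            raise FitError(f"covariates not in table: {missing}")
        if not covariates.is_complete():
            raise FitError(
                "covariate table contains missing values; run preprocess_covariates first"
            )
        keep = frame["panelist"].isin(covariates.panelists)
        frame = frame.loc[keep]
        if frame.empty:
            raise FitError("no durations left after dropping panelists without covariates")
    y = frame["duration"].to_numpy(dtype=float)
    if spec.support_shift:
        y = y - 1.0
    group = frame["group"].to_numpy()
    n = len(frame)
    if spec.uses_covariates and spec.covariates:
        Xc = covariates.frame.loc[
            frame["panelist"].to_list(), list(spec.covariates)
        ].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), Xc])
    else:
        X = np.ones((n, 1))
    return y, X, group


def fit(
    spec: ModelSpec,
    durations: DurationTable,
    scheme: AttributeScheme,
    covariates: CovariateTable | None = None,
) -> DurationFit:
    """Maximum-likelihood fit of one duration family.

    For R/Rg the covariate table must already be preprocessed (complete,
    normalized); panelists absent from it are dropped from the likelihood.
    Grouped families require at least one observed duration in every
    attribute group.
    """
    y, X, group = _design(durations, spec, covariates)
    G = scheme.n_groups
    if spec.grouped:
        blocks = []
        for g in range(G):
            mask = group == g
            if not mask.any():
                raise EmptyGroupError(scheme.group_names[g])
            blocks.append((y[mask], X[mask]))
    else:
        blocks = [(y, X)]

    fix_kappa = 1.0 if spec.family == "G" else None
    betas, kappas, boundary_flags = [], [], []
    total_ll = 0.0
    converged = True
    for yb, Xb in blocks:
        b, k, ll, ok, bflag = _fit_block(yb, Xb, fix_kappa=fix_kappa)
        betas.append(b)
        kappas.append(k)
        boundary_flags.append(bflag)
        total_ll += ll
        converged = converged and ok
    n_params = spec.n_params(G)
    return DurationFit(
        spec=spec,
        scheme=scheme,
        beta=np.vstack(betas),
        kappa=np.asarray(kappas),
        loglik=total_ll,
        n_params=n_params,
        aic=aic(total_ll, n_params),
        converged=converged,
        boundary=np.asarray(boundary_flags),
        n_obs=len(y),
        covariate_names=spec.covariates,
    )


def compare_models(
    fits: Sequence[DurationFit],
) -> pd.DataFrame:
    """Model-comparison table (family, covariates, n_params, loglik, AIC), best first."""
    rows = [
        {
            "family": f.spec.family,
            "covariates": "+".join(f.spec.covariates),
            "n_params": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate subset selection


@dataclass
class SelectionResult:
    best: DurationFit
    ranking: pd.DataFrame


def _rank_key(row: dict) -> tuple:
    return (row["aic"], row["n_params"], row["covariates"])


def select_covariates(
    family: str,
    candidates: Sequence[str],
    durations: DurationTable,
    scheme: AttributeScheme,
    covariates: CovariateTable,
    strategy: str = "exhaustive",
    support_shift: bool = True,
    max_exhaustive: int = 15,
) -> SelectionResult:
    """Choose the covariate subset minimizing AIC for family R or Rg.

    The same subset applies to every attribute group in Rg.  ``exhaustive``
    evaluates all 2^K subsets (K <= ``max_exhaustive``); ``forward`` adds
    greedily while AIC improves.  Ties are broken toward fewer parameters,
    then lexicographic variable order.  Non-converged fits are recorded in
    the ranking but excluded from the choice of best subset.
    """
    if family not in ("R", "Rg"):
        raise ValueError("subset selection applies to families R and Rg")
    candidates = tuple(candidates)

    def fit_subset(subset: tuple[str, ...]) -> DurationFit:
        spec = ModelSpec(family=family, covariates=subset, support_shift=support_shift)
        return fit(spec, durations, scheme, covariates)

    evaluated: dict[tuple[str, ...], DurationFit] = {}

    if strategy == "exhaustive":
        if len(candidates) > max_exhaustive:
            raise ValueError(
                f"{len(candidates)} candidates exceed the exhaustive limit "
                f"{max_exhaustive}; use strategy='forward'"
            )
        for r in range(len(candidates) + 1):
            for subset in itertools.combinations(candidates, r):
                evaluated[subset] = fit_subset(subset)
    elif strategy == "forward":
        current: tuple[str, ...] = ()
        current_fit = fit_subset(current)
        evaluated[current] = current_fit
        remaining = list(candidates)
        while remaining:
            trial_fits = {}
            for var in remaining:
                subset = tuple(v for v in candidates if v in set(current) | {var})
                if subset not in evaluated:
                    evaluated[subset] = fit_subset(subset)
                trial_fits[var] = evaluated[subset]
            ok = {v: f for v, f in trial_fits.items() if f.converged}
            if not ok:
                break
            best_var = min(ok, key=lambda v: (ok[v].aic, v))
            if ok[best_var].aic < current_fit.aic:
                current = tuple(v for v in candidates if v in set(current) | {best_var})
                current_fit = evaluated[current]
                remaining.remove(best_var)
            else:
                break
    else:
        raise ValueError("strategy must be 'exhaustive' or 'forward'")

    rows = []
    for subset, f in evaluated.items():
        rows.append(
            {
                "covariates": "+".join(subset),
                "n_covariates": len(subset),
                "n_params": f.n_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "converged": f.converged,
            }
        )
        if not f.converged:
            warnings.warn(
                f"fit for subset {subset!r} did not converge; excluded from ranking",
                RuntimeWarning,
                stacklevel=2,
            )
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["aic", "n_params", "covariates"], kind="stable")
        .reset_index(drop=True)
    )
    converged_fits = {s: f for s, f in evaluated.items() if f.converged}
    if not converged_fits:
        raise FitError("no candidate subset converged")
    best_subset = min(
        converged_fits,
        key=lambda s: (converged_fits[s].aic, converged_fits[s].n_params, s),
    )
    return SelectionResult(best=converged_fits[best_subset], ranking=ranking)
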