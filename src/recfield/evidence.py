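"""Estimating contact-energy hyperparameters from binary functional data.

The state energies theta are latent: given hyperparameters (mu_P, var_P,
mu_N, var_N), each chimera is functional with probability sigma(-x_c . theta)
and theta has independent Gaussian priors per state class. The energies are
integrated out of the likelihood (the marginalized likelihood, or evidence)
by Laplace's method: a damped Newton solve locates the unique mode of the
strictly concave log posterior, and the Gaussian integral about the mode
supplies the evidence. The four hyperparameters are then chosen to maximize
the evidence by Nelder-Mead from a small multi-start grid, with variances
log-parameterized to stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .field import RandomFieldParams

GRAD_TOL = 1e-8
MAX_NEWTON_ITER = 100


class IdentifiabilityError(ValueError):
    """Raised when the dataset cannot constrain the requested parameters."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class FunctionalDataset:
    """(chimera code, binary functional status) records.

    Duplicate codes with equal status collapse into a weighted record;
    duplicates with conflicting status are rejected.
    """

    codes: tuple[str, ...]
    functional: np.ndarray  # 0/1 per unique code
    weights: np.ndarray  # record multiplicity per unique code

    @classmethod
    def from_records(
        cls, records: list[tuple[str, int]]
    ) -> "FunctionalDataset":
        seen: dict[str, int] = {}
        counts: dict[str, int] = {}
        for code, t in records:
            t = int(t)
            if t not in (0, 1):
                raise ValueError(f"functional status must be 0/1, got {t}")
            if code in seen:
                if seen[code] != t:
                    raise ValueError(
                        f"chimera {code} recorded with conflicting status"
                    )
                counts[code] += 1
            else:
                seen[code] = t
                counts[code] = 1
        codes = tuple(seen)
        return cls(
            codes=codes,
            functional=np.array([seen[c] for c in codes], dtype=float),
            weights=np.array([counts[c] for c in codes], dtype=float),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FunctionalDataset":
        return cls.from_records(
            list(zip(df["chimera"].astype(str), df["functional"].astype(int)))
        )

    def __len__(self) -> int:
        return int(self.weights.sum())


@dataclass
class FitResult:
    params: RandomFieldParams
    log_evidence: float
    map_energies: np.ndarray
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def _log_posterior(theta, X, T, w, prior_mean, prior_var):
    z = X @ theta
    # log Bernoulli with P(T=1) = sigma(-z)
    loglik = np.sum(w * (T * log_expit(-z) + (1.0 - T) * log_expit(z)))
    resid = theta - prior_mean
    logprior = -0.5 * np.sum(
        resid * resid / prior_var + np.log(2.0 * np.pi * prior_var)
    )
    return loglik + logprior


def _map_newton(X, T, w, prior_mean, prior_var, theta0=None):
    """Damped Newton ascent of the strictly concave log posterior.

    Returns (theta*, cho_factor of -Hessian, objective value, n_iter).
    """
    theta = prior_mean.copy() if theta0 is None else theta0.copy()
    f = _log_posterior(theta, X, T, w, prior_mean, prior_var)
    n_iter = 0
    for n_iter in range(1, MAX_NEWTON_ITER + 1):
        z = X @ theta
        p = expit(-z)  # P(T = 1)
        grad = X.T @ (w * (p - T)) - (theta - prior_mean) / prior_var
        if np.max(np.abs(grad)) < GRAD_TOL:
            break
        d = w * p * (1.0 - p)
        A = (X.T * d) @ X
        A[np.diag_indices_from(A)] += 1.0 / prior_var
        chol = cho_factor(A, lower=True)
        step = cho_solve(chol, grad)
        # Newton decrement: scale-free stopping rule that stays meaningful
        # when near-delta priors blow up the raw gradient scale
        if 0.5 * float(grad @ step) < 1e-20:
            break
        t = 1.0
        for _ in range(50):
            cand = theta + t * step
            f_cand = _log_posterior(cand, X, T, w, prior_mean, prior_var)
            if f_cand >= f:
                break
            t *= 0.5
        else:
            raise ConvergenceError(
                "Newton line search failed",
                {"iter": n_iter, "grad_inf": float(np.max(np.abs(grad)))},
            )
        theta, f = cand, f_cand
    else:
        z = X @ theta
        p = expit(-z)
        grad = X.T @ (w * (p - T)) - (theta - prior_mean) / prior_var
        d = w * p * (1.0 - p)
        A = (X.T * d) @ X
        A[np.diag_indices_from(A)] += 1.0 / prior_var
        step = cho_solve(cho_factor(A, lower=True), grad)
        if (
            np.max(np.abs(grad)) >= GRAD_TOL
            and 0.5 * float(grad @ step) >= 1e-20
        ):
            raise ConvergenceError(
                "Newton did not converge",
                {
                    "iter": MAX_NEWTON_ITER,
                    "grad_inf": float(np.max(np.abs(grad))),
                },
            )
    # -Hessian at the optimum, for the Laplace curvature term
    z = X @ theta
    p = expit(-z)
    d = w * p * (1.0 - p)
    A = (X.T * d) @ X
    A[np.diag_indices_from(A)] += 1.0 / prior_var
    chol = cho_factor(A, lower=True)
    return theta, chol, f, n_iter


def _priors_from_params(params, novel, multiplicity=None):
    mean = params.state_means(novel).astype(float)
    var = params.state_vars(novel).astype(float)
    if multiplicity is not None:
        # m identical columns with iid priors integrate exactly to one
        # column whose summed energy has an m-fold wider Gaussian prior
        mean = mean * multiplicity
        var = var * multiplicity
    return mean, var


def find_map_energies(
    params: RandomFieldParams,
    X: np.ndarray,
    T: np.ndarray,
    novel: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mode state energies theta* and the Hessian there.

    With no observations theta* equals the prior means exactly.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    w = np.ones(len(T)) if weights is None else np.asarray(weights, float)
    prior_mean, prior_var = _priors_from_params(params, novel)
    if X.shape[0] == 0:
        return prior_mean, np.diag(-1.0 / prior_var)
    theta, chol, _, _ = _map_newton(X, T, w, prior_mean, prior_var)
    z = X @ theta
    p = expit(-z)
    d = w * p * (1.0 - p)
    H = -((X.T * d) @ X) - np.diag(1.0 / prior_var)
    return theta, H


def log_marginal_likelihood(
    params: RandomFieldParams,
    X: np.ndarray,
    T: np.ndarray,
    novel: np.ndarray,
    weights: np.ndarray | None = None,
    multiplicity: np.ndarray | None = None,
) -> float:
    """Laplace-approximated log evidence of the binary data.

    log p(T | params) ~= log p(T, theta*) + (d/2) log 2 pi
    - (1/2) log det(-H), with d the number of energy dimensions integrated
    (the columns of X) and H the log-posterior Hessian at the mode theta*.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    w = np.ones(len(T)) if weights is None else np.asarray(weights, float)
    prior_mean, prior_var = _priors_from_params(params, novel, multiplicity)
    theta, chol, f, _ = _map_newton(X, T, w, prior_mean, prior_var)
    d = X.shape[1]
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    return float(f + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet)


def collapse_identical_states(
    X: np.ndarray, novel: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge identical (column, label) pairs; returns (Xc, novel_c, mult).

    Columns with identical indicators and the same P/N label enter the
    likelihood only through their summed energy, whose prior is Gaussian
    with m-fold mean and variance — an exact reduction of the evidence
    integral that shrinks the Newton system considerably (conserved
    contacts all share one all-ones column).
    """
    keys = {}
    order = []
    for s in range(X.shape[1]):
        key = (bool(novel[s]), X[:, s].tobytes())
        if key not in keys:
            keys[key] = len(order)
            order.append([s, 1])
        else:
            order[keys[key]][1] += 1
    idx = np.array([s for s, _ in order])
    mult = np.array([m for _, m in order], dtype=float)
    return X[:, idx].copy(), novel[idx].copy(), mult


DEFAULT_INIT_GRID = tuple(
    (mu_p, mu_n, v, v)
    for mu_p in (-1.0, 0.5)
    for mu_n in (0.5, 2.0)
    for v in (0.25, 4.0)
)


def fit_params(
    X: np.ndarray,
    T: np.ndarray,
    novel: np.ndarray,
    weights: np.ndarray | None = None,
    init_grid: tuple | None = None,
    seed: int = 0,
    maxfev: int = 2000,
    tol: float = 1e-6,
    collapse: bool = True,
    var_bounds: tuple[float, float] = (0.01, 4.0),
) -> FitResult:
    """Maximize the Laplace evidence over (mu_P, mu_N, log var_P, log var_N).

    Nelder-Mead is run from every point of *init_grid* (default: an
    8-point grid spanning stabilizing/destabilizing means and small/large
    variances) and the best optimum is returned. Requires both functional
    and nonfunctional records and at least one novel-state column.

    The variance search is confined to *var_bounds* (kT^2). Laplace's
    method overestimates the evidence when prior variances grow large
    (the energy posterior turns strongly non-Gaussian as the logistic
    likelihood saturates), which can manufacture spurious
    high-variance optima; per-contact energy spreads beyond ~2 kT are
    also outside the physical regime of marginally stable proteins. The
    default upper bound matches the top of the initialization grid.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    novel = np.asarray(novel, dtype=bool)
    w = np.ones(len(T)) if weights is None else np.asarray(weights, float)
    if T.min() == T.max():
        raise IdentifiabilityError(
            "all records share one functional status; the energy scale "
            "is unidentifiable"
        )
    if not novel.any():
        raise IdentifiabilityError(
            "no novel states realized: mu_N/var_N unidentifiable"
        )
    if collapse:
        Xc, novel_c, mult = collapse_identical_states(X, novel)
    else:
        Xc, novel_c, mult = X, novel, None

    warm: dict = {"theta": None}
    n_eval = {"count": 0}

    lv_lo = np.log(var_bounds[0]) - 1e-9
    lv_hi = np.log(var_bounds[1]) + 1e-9

    def neg_log_ev(x):
        mu_p, mu_n, logv_p, logv_n = x
        if not (
            lv_lo <= logv_p <= lv_hi
            and lv_lo <= logv_n <= lv_hi
            and abs(mu_p) <= 50
            and abs(mu_n) <= 50
        ):
            return 1e12
        params = RandomFieldParams(mu_p, np.exp(logv_p), mu_n, np.exp(logv_n))
        prior_mean, prior_var = _priors_from_params(params, novel_c, mult)
        try:
            theta, chol, f, _ = _map_newton(
                Xc, T, w, prior_mean, prior_var, theta0=warm["theta"]
            )
        except ConvergenceError:
            try:
                theta, chol, f, _ = _map_newton(
                    Xc, T, w, prior_mean, prior_var
                )
            except ConvergenceError:
                return 1e12
        warm["theta"] = theta
        n_eval["count"] += 1
        d = Xc.shape[1]
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        return -(f + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet)

    grid = DEFAULT_INIT_GRID if init_grid is None else init_grid
    # explicit initial simplex: scipy's default perturbs zero coordinates
    # by 2.5e-4, far too small for log-variance directions
    steps = np.array([0.3, 0.3, 0.5, 0.5])
    rows = []
    best = None
    for mu_p, mu_n, v_p, v_n in grid:
        warm["theta"] = None
        x0 = np.array([mu_p, mu_n, np.log(v_p), np.log(v_n)])
        simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(4)[i] for i in range(4)])
        res = minimize(
            neg_log_ev,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": tol,
                "fatol": tol,
                "maxfev": maxfev,
                "adaptive": False,
                "initial_simplex": simplex,
            },
        )
        rows.append(
            {
                "init": (mu_p, mu_n, v_p, v_n),
                "log_evidence": -float(res.fun),
                "nfev": int(res.nfev),
                "success": bool(res.success),
            }
        )
        if best is None or -res.fun > -best.fun:
            best = res
    mu_p, mu_n, logv_p, logv_n = best.x
    params = RandomFieldParams(mu_p, float(np.exp(logv_p)), mu_n, float(np.exp(logv_n)))
    prior_mean, prior_var = _priors_from_params(params, novel_c, mult)
    theta, chol, f, n_iter = _map_newton(Xc, T, w, prior_mean, prior_var)
    return FitResult(
        params=params,
        log_evidence=-float(best.fun),
        map_energies=theta,
        converged=bool(best.success),
        diagnostics={
            "starts": rows,
            "n_evaluations": n_eval["count"],
            "final_newton_iterations": n_iter,
            "n_energy_dimensions": int(Xc.shape[1]),
            "collapsed": collapse,
            "seed": seed,
        },
    )


def fit_from_dataset(dataset: FunctionalDataset, table, **kwargs) -> FitResult:
    """Fit hyperparameters from a dataset resolved against a state table."""
    X, novel = table.design_matrix_for(list(dataset.codes))
    return fit_params(
        X, dataset.functional, novel, weights=dataset.weights, **kwargs
    )
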