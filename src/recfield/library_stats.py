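"""Library-level statistics: energy moments, fraction functional, additivity.

For a fixed energy landscape, the energies within a recombination library
are treated as Gaussian with library mean m_L and variance v_L, and the
fraction of functional sequences is the Gaussian CDF at zero,
F_L = Phi(-m_L / sqrt(v_L)). Integrating over the random field gives the
expected moments E[m_L] = k mu_P + <n_c> (mu_N - mu_P) and E[v_L] (exact,
from the shared-state covariance algebra), and the leading-order expected
fraction functional E[F_L] ~= Phi(-E[m_L] / sqrt(E[v_L])).

The additivity A = v_add / v_L is the fraction of the library's energy
variance explained by per-block additive effects; on the balanced full
factorial it equals the coefficient of determination of the block-indicator
least-squares fit. 1 - A is the epistatic fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alignment import LibraryDesign, enumerate_assignments
from .contacts import ContactStateTable
from .field import RandomFieldParams, expected_energies


@dataclass
class LibrarySummary:
    """Realized and expected library moments and derived quantities."""

    m_L: float | None = None
    v_L: float | None = None
    F_L: float | None = None
    E_mL: float | None = None
    E_vL: float | None = None
    E_FL: float | None = None
    v_add: float | None = None
    A: float | None = None
    E_A: float | None = None


def library_moments(energies: np.ndarray) -> tuple[float, float]:
    """Population mean and variance of library energies."""
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        raise ValueError("empty library")
    return float(energies.mean()), float(energies.var())


def fraction_functional(m_L: float, v_L: float) -> float:
    """Gaussian CDF at zero: Phi((0 - m_L) / sqrt(v_L)).

    The degenerate v_L = 0 case collapses to an indicator on the sign of
    m_L (0.5 at m_L = 0).
    """
    if v_L < 0:
        raise ValueError("variance must be non-negative")
    if v_L == 0:
        return 0.5 if m_L == 0 else float(m_L < 0)
    return float(norm.cdf(-m_L / np.sqrt(v_L)))


def expected_moments(
    table: ContactStateTable, params: RandomFieldParams
) -> tuple[float, float]:
    """Exact E[m_L] and E[v_L] under the random field.

    E[v_L] decomposes as the variance across the library of the expected
    energies plus sum_s var_s p_s (1 - p_s), where p_s is the fraction of
    the library realizing state s: a state shared by everyone or no one
    contributes nothing to the across-library variance.
    """
    mean_energy = expected_energies(table, params)
    E_mL = float(mean_energy.mean())
    p_s = table.state_occupancy()
    var_s = params.state_vars(table.is_novel)
    E_vL = float(mean_energy.var() + np.sum(var_s * p_s * (1.0 - p_s)))
    return E_mL, E_vL


def expected_fraction_functional(
    table: ContactStateTable, params: RandomFieldParams
) -> float:
    """Leading-order E[F_L]: the F_L formula at the expected moments."""
    E_mL, E_vL = expected_moments(table, params)
    return fraction_functional(E_mL, E_vL)


def _block_parent_means(
    energies: np.ndarray, assignments: np.ndarray, p: int
) -> np.ndarray:
    """(B, p) mean energy over chimeras with block b taken from parent u."""
    B = assignments.shape[1]
    out = np.empty((B, p))
    for b in range(B):
        for u in range(1, p + 1):
            out[b, u - 1] = energies[assignments[:, b] == u].mean()
    return out


def additive_predictor(
    energies: np.ndarray, assignments: np.ndarray, p: int
) -> np.ndarray:
    """Grand mean + per-block main effects, for the balanced full factorial."""
    grand = energies.mean()
    means = _block_parent_means(energies, assignments, p)
    effects = means - grand
    B = assignments.shape[1]
    pred = np.full(energies.shape, grand)
    for b in range(B):
        pred += effects[b, assignments[:, b] - 1]
    return pred


def additive_decomposition(
    energies: np.ndarray, design: LibraryDesign, p: int
) -> tuple[float, float]:
    """(v_add, A) on a full factorial library, lexicographic code order.

    v_add is the population variance of the additive (main-effects)
    predictor; A = v_add / v_L. For the balanced factorial this equals the
    block-indicator least-squares R^2. A constant library returns A = 1
    (nothing left to explain).
    """
    energies = np.asarray(energies, dtype=float)
    B = design.n_blocks
    L = energies.size
    p_guess = round(L ** (1.0 / B))
    if p_guess**B != L or p_guess != p:
        raise ValueError(
            "additive_decomposition requires the full p^B factorial in "
            "lexicographic order; use regression_additivity for sampled data"
        )
    assignments = enumerate_assignments(p, B)
    pred = additive_predictor(energies, assignments, p)
    v_add = float(pred.var())
    v_L = float(energies.var())
    if v_L == 0.0:
        return 0.0, 1.0
    return v_add, min(v_add / v_L, 1.0)


def _centered_additive_part(
    vec: np.ndarray, assignments: np.ndarray, p: int
) -> np.ndarray:
    """Additive predictor minus grand mean — a linear operator on vec."""
    return additive_predictor(vec, assignments, p) - vec.mean()


def expected_additive_variance(
    table: ContactStateTable, params: RandomFieldParams
) -> float:
    """Exact E[v_add] over the random field.

    v_add(theta) is a quadratic form in the state energies: with A the
    centered-additive-part projection and X the indicator matrix,
    v_add = ||A X theta||^2 / L, so its expectation is
    (||A X mu||^2 + sum_s var_s ||A x_s||^2) / L.
    """
    p = table.alignment.n_parents
    assignments = table.assignments
    L = table.n_chimeras
    mean_energy = expected_energies(table, params)
    acc = np.sum(_centered_additive_part(mean_energy, assignments, p) ** 2)
    var_s = params.state_vars(table.is_novel)
    X = table.indicator_matrix().astype(float)
    for s in range(table.n_states):
        acc += var_s[s] * np.sum(
            _centered_additive_part(X[:, s], assignments, p) ** 2
        )
    return float(acc / L)


def expected_additivity(
    table: ContactStateTable,
    params: RandomFieldParams,
    n_draws: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """(E_A, standard error): leading-order E[v_add] / E[v_L].

    With n_draws = 0 both moments are computed exactly from the covariance
    algebra (SE = 0). With n_draws > 0 the numerator is estimated by Monte
    Carlo over seeded landscape draws, each decomposed on the full
    factorial; the reported SE propagates the numerator's sampling error.
    """
    _, E_vL = expected_moments(table, params)
    if E_vL == 0.0:
        return 1.0, 0.0
    if n_draws <= 0:
        return expected_additive_variance(table, params) / E_vL, 0.0
    from .field import sample_energy_matrix

    energies = sample_energy_matrix(table, params, n_draws, seed)
    p = table.alignment.n_parents
    v_adds = np.empty(n_draws)
    for r in range(n_draws):
        pred = additive_predictor(energies[r], table.assignments, p)
        v_adds[r] = pred.var()
    est = float(v_adds.mean() / E_vL)
    se = float(v_adds.std(ddof=1) / np.sqrt(n_draws) / E_vL)
    return est, se


def regression_additivity(
    dataset: pd.DataFrame, design: LibraryDesign, p: int
) -> float:
    """In-sample R^2 of the block-based linear regression of a property.

    *dataset* must have columns ``chimera`` (digit code) and ``value``.
    The design matrix holds reference-coded parent indicators per block
    plus an intercept; rank deficiency (unobserved block-parent
    combinations) raises with the missing combinations listed.
    """
    import statsmodels.api as sm

    codes = dataset["chimera"].astype(str).tolist()
    y = dataset["value"].to_numpy(dtype=float)
    B = design.n_blocks
    if len(codes) < B * (p - 1) + 2:
        raise ValueError("too few records for the block regression")
    missing = [
        (b + 1, u)
        for b in range(B)
        for u in range(1, p + 1)
        if not any(int(c[b]) == u for c in codes)
    ]
    if missing:
        raise ValueError(
            f"unobserved block-parent combinations: {missing}"
        )
    cols = []
    for b in range(B):
        for u in range(2, p + 1):  # parent 1 is the reference level
            cols.append([1.0 if int(c[b]) == u else 0.0 for c in codes])
    Xmat = sm.add_constant(np.array(cols).T, has_constant="add")
    fit = sm.OLS(y, Xmat).fit()
    return float(fit.rsquared)
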