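"""The Gaussian random field over the parental subspace.

Each distinct (contact, residue-pair state) carries an independent Gaussian
energy term: parental states ~ N(mu_P, var_P), novel states ~ N(mu_N,
var_N), in kT units. A chimera's energy is the sum of its realized state
energies, interpreted as the Gibbs free-energy difference between the
functional and nonfunctional forms, so P(functional) is the logistic
sigmoid of minus the energy (the two-state Boltzmann weight). Sharing of
state terms between chimeras induces the field's covariance structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .contacts import ContactStateTable


@dataclass(frozen=True)
class RandomFieldParams:
    """Contact-energy hyperparameters (kT units)."""

    mu_P: float
    var_P: float
    mu_N: float
    var_N: float

    def __post_init__(self) -> None:
        if not (self.var_P > 0 and self.var_N > 0):
            raise ValueError("variances must be positive")
        vals = (self.mu_P, self.var_P, self.mu_N, self.var_N)
        if not all(np.isfinite(vals)):
            raise ValueError("parameters must be finite")

    def state_means(self, is_novel: np.ndarray) -> np.ndarray:
        return np.where(is_novel, self.mu_N, self.mu_P)

    def state_vars(self, is_novel: np.ndarray) -> np.ndarray:
        return np.where(is_novel, self.var_N, self.var_P)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu_P": self.mu_P,
                "var_P": self.var_P,
                "mu_N": self.mu_N,
                "var_N": self.var_N,
                "units": "kT",
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RandomFieldParams":
        d = json.loads(text)
        return cls(d["mu_P"], d["var_P"], d["mu_N"], d["var_N"])


@dataclass(frozen=True)
class EnergyRealization:
    """One draw of all state energies and the induced chimera energies."""

    theta: np.ndarray  # energy per global state, contact-major order
    energies: np.ndarray  # per-chimera total energy, library row order
    seed: int


def expected_energy(
    chimera_row: int, table: ContactStateTable, params: RandomFieldParams
) -> float:
    """Mean field at one chimera: (k - n_c) mu_P + n_c mu_N."""
    n_c = int(table.is_novel[table.state_of[chimera_row]].sum())
    return (table.k - n_c) * params.mu_P + n_c * params.mu_N


def expected_energies(
    table: ContactStateTable, params: RandomFieldParams
) -> np.ndarray:
    """Mean field at every chimera of the library."""
    n_c = table.n_c
    return (table.k - n_c) * params.mu_P + n_c * params.mu_N


def energy_covariance(
    row1: int, row2: int, table: ContactStateTable, params: RandomFieldParams
) -> float:
    """Covariance of two chimera energies under the field.

    Equals var_P times the number of contacts where both realize the same
    parental state plus var_N times the number of shared novel states.
    """
    s1, s2 = table.state_of[row1], table.state_of[row2]
    shared = s1 == s2
    novel = table.is_novel[s1]
    n_shared_novel = int((shared & novel).sum())
    n_shared_par = int(shared.sum()) - n_shared_novel
    return params.var_P * n_shared_par + params.var_N * n_shared_novel


def prob_functional(
    chimera_row: int, table: ContactStateTable, params: RandomFieldParams
) -> float:
    """Logistic sigmoid evaluated at minus the expected energy."""
    return float(expit(-expected_energy(chimera_row, table, params)))


def prob_functional_all(
    table: ContactStateTable, params: RandomFieldParams
) -> np.ndarray:
    """sigma(-E[energy]) for every chimera of the library."""
    return expit(-expected_energies(table, params))


def sample_energy_realization(
    table: ContactStateTable,
    params: RandomFieldParams,
    seed: int,
) -> EnergyRealization:
    """Draw one landscape: independent state energies, summed per chimera.

    State draws are ordered by (contact index, state index) so the same
    seed reproduces the same realization on any platform.
    """
    rng = np.random.default_rng(seed)
    mu = params.state_means(table.is_novel)
    sd = np.sqrt(params.state_vars(table.is_novel))
    theta = mu + sd * rng.standard_normal(table.n_states)
    energies = theta[table.state_of].sum(axis=1)
    return EnergyRealization(theta=theta, energies=energies, seed=seed)


def sample_energy_matrix(
    table: ContactStateTable,
    params: RandomFieldParams,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """(n_draws, L) chimera energies over independent landscape draws."""
    rng = np.random.default_rng(seed)
    mu = params.state_means(table.is_novel)
    sd = np.sqrt(params.state_vars(table.is_novel))
    theta = mu + sd * rng.standard_normal((n_draws, table.n_states))
    X = table.indicator_matrix().astype(float)
    return theta @ X.T
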