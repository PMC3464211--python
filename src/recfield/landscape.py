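"""Substitution-curve analyses, tolerance fitting, and library sampling.

The fraction of functional sequences declines roughly exponentially with
random mutations but log-parabolically with homologous substitutions,
because accumulating substitutions from another functional parent must
eventually reconstruct that parent. The recombinational tolerance rho —
the modeled probability that a single homologous substitution preserves
function — is read off a log-parabolic fit to the substitution curve.
Random-library sampling plus a nested variance decomposition apportions
the variation in expected fraction functional among protein fold, parent
identity, and crossover locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import beta

from .alignment import (
    AMINO_ACIDS,
    GAP,
    LibraryDesign,
    ParentAlignment,
    chimera_sequence,
    enumerate_library,
    substitutions_to_closest_parent,
)
from .contacts import ContactMap, ContactStateTable, classify_sequence_contacts
from .field import RandomFieldParams, prob_functional_all

logger = logging.getLogger(__name__)


@dataclass
class SubstitutionCurve:
    """Mean probability of function binned by substitution count."""

    mode: str  # recombination | random_mutation | random_homologous
    bin_edges: np.ndarray  # len = n_bins + 1
    bin_centers: np.ndarray
    mean_prob: np.ndarray
    counts: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "m_center": self.bin_centers,
                "mean_prob_functional": self.mean_prob,
                "count": self.counts,
            }
        )


@dataclass
class ToleranceFit:
    """Log-parabolic substitution-curve fit.

    The fitted form is ln P(m) = lambda * m (D - m) / (D - 1), which pins
    P(0) = P(D) = 1 and makes rho = exp(lambda) the modeled probability
    that a single homologous substitution (m = 1) preserves function.
    """

    rho: float
    lam: float
    D: int
    residuals: np.ndarray
    n_bins_used: int


@dataclass
class VarianceComponents:
    """Fractions of E[F_L] variance from nested library sampling."""

    parent_identity: float
    crossover_locations: float
    protein_fold: float
    residual: float

    def as_dict(self) -> dict[str, float]:
        return {
            "parent_identity": self.parent_identity,
            "crossover_locations": self.crossover_locations,
            "protein_fold": self.protein_fold,
            "residual": self.residual,
        }


def _bin_curve(m, probs, n_bins, mode):
    m = np.asarray(m, dtype=float)
    probs = np.asarray(probs, dtype=float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, m, side="right") - 1, 0, n_bins - 1)
    mean_prob = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            mean_prob[b] = probs[mask].mean()
    return SubstitutionCurve(
        mode=mode,
        bin_edges=edges,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_prob=mean_prob,
        counts=counts,
    )


def recombination_curve(
    alignment: ParentAlignment,
    design: LibraryDesign,
    table: ContactStateTable,
    params: RandomFieldParams,
    n_bins: int = 15,
    max_chimeras: int = 100_000,
    seed: int = 0,
) -> SubstitutionCurve:
    """Bin sigma(-E[energy]) of every library chimera by its substitution
    count to the closest parent, in *n_bins* equal-width groups.

    Libraries above *max_chimeras* are represented by a uniform sample of
    that size (logged, reproducible under *seed*).
    """
    probs = prob_functional_all(table, params)
    chimeras = enumerate_library(alignment, design)
    if len(chimeras) > max_chimeras:
        rng = np.random.default_rng(seed)
        rows = rng.choice(len(chimeras), size=max_chimeras, replace=False)
        logger.warning(
            "library of %d chimeras sampled down to %d (seed %d)",
            len(chimeras), max_chimeras, seed,
        )
        chimeras = [chimeras[r] for r in rows]
        probs = probs[rows]
    m = [
        substitutions_to_closest_parent(
            chimera_sequence(c, alignment, design), alignment
        )
        for c in chimeras
    ]
    return _bin_curve(m, probs, n_bins, "recombination")


def min_novel_substitution_probability(alignment: ParentAlignment) -> float:
    """Min over columns of P(uniform random substitution hits a residue
    absent from every parent).

    At a column where parents show r distinct residues, a substitution is
    drawn uniformly from the 19 residues other than the current one, of
    which 20 - r appear in no parent.
    """
    arr = alignment.as_array()
    best = 1.0
    for col in range(alignment.length):
        residues = set(arr[:, col]) - {GAP}
        if not residues:
            continue
        best = min(best, (20 - len(residues)) / 19.0)
    return best


def random_mutation_curve(
    alignment: ParentAlignment,
    contact_map: ContactMap,
    params: RandomFieldParams,
    m_max: int,
    samples_per_m: int = 100,
    seed: int = 0,
    reference_parent: int = 1,
) -> SubstitutionCurve:
    """Mean probability of function of random mutants of one parent.

    For each m, *samples_per_m* mutants carry m uniformly placed random
    substitutions (to a uniform non-current residue); every contact is
    re-classified against the parents (parental iff the realized pair
    occurs in some parent) and sigma(-E[energy]) is averaged.
    """
    rng = np.random.default_rng(seed)
    ref = alignment.rows[reference_parent - 1]
    positions = [i for i, ch in enumerate(ref) if ch != GAP]
    if m_max > len(positions):
        raise ValueError("m_max exceeds the number of mutable positions")
    centers, means = [], []
    for m in range(m_max + 1):
        probs = np.empty(samples_per_m if m else 1)
        for s in range(len(probs)):
            seq = list(ref)
            for pos in rng.choice(positions, size=m, replace=False):
                current = seq[pos]
                options = [a for a in AMINO_ACIDS if a != current]
                seq[pos] = options[rng.integers(len(options))]
            n_p, n_n = classify_sequence_contacts(
                "".join(seq), alignment, contact_map
            )
            energy = n_p * params.mu_P + n_n * params.mu_N
            probs[s] = expit(-energy)
        centers.append(m)
        means.append(probs.mean())
    centers = np.array(centers, dtype=float)
    return SubstitutionCurve(
        mode="random_mutation",
        bin_edges=np.concatenate([centers - 0.5, [centers[-1] + 0.5]]),
        bin_centers=centers,
        mean_prob=np.array(means),
        counts=np.array([1] + [samples_per_m] * m_max),
    )


def random_homologous_curve(
    alignment: ParentAlignment,
    contact_map: ContactMap,
    params: RandomFieldParams,
    samples_per_m: int = 100,
    seed: int = 0,
    reference_parent: int = 1,
) -> SubstitutionCurve:
    """Mean probability of function under scattered homologous substitutions.

    For each m up to the number of variable positions, m positions where
    another parent differs from the reference are switched to a (randomly
    chosen) other parent's residue — the same substitutions recombination
    makes, but without the contiguity of blocks.
    """
    rng = np.random.default_rng(seed)
    arr = alignment.as_array()
    ref_idx = reference_parent - 1
    others = [u for u in range(alignment.n_parents) if u != ref_idx]
    variable = [
        i
        for i in range(alignment.length)
        if any(arr[u, i] != arr[ref_idx, i] for u in others)
    ]
    D = len(variable)
    centers, means = [], []
    for m in range(D + 1):
        probs = np.empty(samples_per_m if 0 < m < D else 1)
        for s in range(len(probs)):
            seq = arr[ref_idx].copy()
            for pos in rng.choice(variable, size=m, replace=False):
                choices = [
                    arr[u, pos] for u in others if arr[u, pos] != seq[pos]
                ]
                seq[pos] = choices[rng.integers(len(choices))]
            n_p, n_n = classify_sequence_contacts(
                "".join(seq), alignment, contact_map
            )
            energy = n_p * params.mu_P + n_n * params.mu_N
            probs[s] = expit(-energy)
        centers.append(m)
        means.append(probs.mean())
    centers = np.array(centers, dtype=float)
    return SubstitutionCurve(
        mode="random_homologous",
        bin_edges=np.concatenate([centers - 0.5, [centers[-1] + 0.5]]),
        bin_centers=centers,
        mean_prob=np.array(means),
        counts=np.array(
            [1] + [samples_per_m] * max(D - 1, 0) + ([1] if D else [])
        ),
    )


def fit_log_parabola(curve: SubstitutionCurve, D: int) -> ToleranceFit:
    """Least-squares fit of ln P(m) = lambda m (D - m) / (D - 1).

    Bins with nonpositive or undefined probabilities are dropped with a
    warning; at least 3 usable bins are required. The regression has no
    intercept: P(0) = P(D) = 1 by construction.
    """
    if D < 2:
        raise ValueError("parent distance D must be at least 2")
    mask = np.isfinite(curve.mean_prob) & (curve.mean_prob > 0)
    dropped = int((~mask & (curve.counts > 0)).sum())
    if dropped:
        logger.warning("dropped %d bins with nonpositive probability", dropped)
    m = curve.bin_centers[mask]
    lnp = np.log(curve.mean_prob[mask])
    if len(m) < 3:
        raise ValueError("fewer than 3 usable bins for the log-parabola fit")
    g = m * (D - m) / (D - 1.0)
    lam = float(np.sum(g * lnp) / np.sum(g * g))
    return ToleranceFit(
        rho=float(np.exp(lam)),
        lam=lam,
        D=D,
        residuals=lnp - lam * g,
        n_bins_used=int(mask.sum()),
    )


def sample_random_alignment(
    M: int, p: int, identity: float, seed: int
) -> ParentAlignment:
    """Random gapless parents with target expected pairwise identity.

    Each column is conserved with probability c, otherwise all parents
    draw uniform residues conditioned on not all being equal. For p > 2
    accidental pairwise matches in nonconserved columns are corrected for
    by solving c + (1 - c) q = identity, with q the accidental match rate.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_aa = len(AMINO_ACIDS)
    p_all_equal = n_aa ** (1 - p)
    q = (1.0 / n_aa - p_all_equal) / (1.0 - p_all_equal)
    c = (identity - q) / (1.0 - q)
    c = min(max(c, 0.0), 1.0)
    aa = np.array(list(AMINO_ACIDS))
    cols = np.empty((p, M), dtype="U1")
    conserved = rng.random(M) < c
    for i in range(M):
        if conserved[i]:
            cols[:, i] = aa[rng.integers(n_aa)]
        else:
            while True:
                draw = aa[rng.integers(n_aa, size=p)]
                if not np.all(draw == draw[0]):
                    break
            cols[:, i] = draw
    rows = tuple("".join(cols[u]) for u in range(p))
    ids = tuple(f"parent{u + 1}" for u in range(p))
    return ParentAlignment(parent_ids=ids, rows=rows)


def sample_random_crossovers(
    M: int, n: int, min_block: int = 1, seed: int = 0
) -> LibraryDesign:
    """Uniform random crossover design honoring a minimum block length.

    Uniform over valid designs via the stars-and-bars bijection: block
    lengths are min_block plus a uniform weak composition of the slack.
    """
    B = n + 1
    if n > M - 1:
        raise ValueError("more crossovers than internal boundaries")
    slack = M - B * min_block
    if slack < 0:
        raise ValueError("min_block infeasible for this M and n")
    rng = np.random.default_rng(seed)
    if n == 0:
        return LibraryDesign(length=M, crossovers=())
    # choose n sorted cut points among slack + n positions, then re-add
    # the mandatory min_block runs
    cuts = np.sort(rng.choice(slack + n, size=n, replace=False)) + 1
    extras = np.diff(np.concatenate([[0], cuts])) - 1
    lengths = extras + min_block
    xs = np.cumsum(lengths)
    return LibraryDesign(length=M, crossovers=tuple(int(x) for x in xs))


def variance_components_experiment(
    folds: list[ContactMap],
    identities: np.ndarray,
    n_libraries: int,
    n_crossovers: int,
    params: RandomFieldParams,
    seed: int,
    p: int = 2,
) -> tuple[VarianceComponents, np.ndarray]:
    """Nested sampling of (fold, alignment, library) and E[F_L] decomposition.

    For each fold (contact map), one random two-parent alignment per
    identity level and *n_libraries* random crossover designs per
    alignment; E[F_L] is computed for every cell. Nested sums of squares
    attribute between-fold variance to the protein fold, between-alignment
    (within fold) variance to parent identity, and between-library (within
    alignment) variance to crossover locations; with one value per cell
    the residual is zero.
    """
    from .contacts import classify_states
    from .library_stats import expected_fraction_functional

    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    if len(identities) < 2:
        raise ValueError("need at least 2 identity levels")
    ss = np.random.SeedSequence(seed)
    values = np.empty((len(folds), len(identities), n_libraries))
    for f, cmap in enumerate(folds):
        for a, ident in enumerate(identities):
            child = ss.spawn(1)[0]
            aln_seed, lib_seed0 = child.generate_state(2) >> 1  # < 2^31
            aln = sample_random_alignment(cmap.length, p, float(ident), int(aln_seed))
            for l in range(n_libraries):
                design = sample_random_crossovers(
                    cmap.length, n_crossovers, seed=int(lib_seed0) + l
                )
                table = classify_states(aln, design, cmap)
                values[f, a, l] = expected_fraction_functional(table, params)
    total = float(((values - values.mean()) ** 2).sum())
    if total == 0.0:
        raise ValueError("zero total variance: degenerate experiment")
    fold_means = values.mean(axis=(1, 2))
    aln_means = values.mean(axis=2)
    n_per_fold = values.shape[1] * values.shape[2]
    ss_fold = float(n_per_fold * ((fold_means - values.mean()) ** 2).sum())
    ss_aln = float(
        values.shape[2]
        * ((aln_means - fold_means[:, None]) ** 2).sum()
    )
    ss_lib = float(((values - aln_means[:, :, None]) ** 2).sum())
    comps = VarianceComponents(
        parent_identity=ss_aln / total,
        crossover_locations=ss_lib / total,
        protein_fold=ss_fold / total,
        residual=max(0.0, 1.0 - (ss_aln + ss_lib + ss_fold) / total),
    )
    return comps, values


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("invalid counts")
    alpha = 1.0 - level
    lower = (
        0.0
        if successes == 0
        else float(beta.ppf(alpha / 2, successes, trials - successes + 1))
    )
    upper = (
        1.0
        if successes == trials
        else float(beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    )
    return lower, upper


def construction_error_correction(
    n_functional: int,
    n_assayed: int,
    frameshift_obs: tuple[int, int] = (9, 13),
    level: float = 0.95,
) -> dict:
    """Correct a library's fraction functional for construction errors.

    Sequencing *frameshift_obs* = (frameshifted, sequenced) unselected
    clones estimates the correctly-constructed proportion
    q = (sequenced - frameshifted) / sequenced with a Clopper-Pearson
    interval; the corrected fraction functional is
    n_functional / (q * n_assayed), with its interval obtained by
    evaluating at the q interval endpoints (capped at 1).
    """
    if min(n_functional, n_assayed) < 0 or n_functional > n_assayed:
        raise ValueError("invalid counts")
    shifted, sequenced = frameshift_obs
    correct = sequenced - shifted
    q_hat = correct / sequenced
    if q_hat == 0.0:
        raise ValueError("no correctly constructed clones observed")
    q_lo, q_hi = clopper_pearson(correct, sequenced, level)
    raw = n_functional / n_assayed
    corrected = raw / q_hat
    ci = (
        min(raw / q_hi, 1.0) if q_hi > 0 else 1.0,
        min(raw / q_lo, 1.0) if q_lo > 0 else 1.0,
    )
    return {
        "q_hat": q_hat,
        "q_interval": (q_lo, q_hi),
        "raw_fraction": raw,
        "corrected_fraction": min(corrected, 1.0),
        "corrected_interval": ci,
    }
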