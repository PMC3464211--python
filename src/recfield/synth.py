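"""Synthetic recombination systems with the model's generative structure.

Everything a study of the recombinational landscape needs — parent
alignments, contact maps, crossover designs, true contact energies,
Bernoulli functional outcomes, and additive-plus-epistatic property data —
is generated from explicit seeds, so every stage of the pipeline is
testable without structure downloads. A system carries one fixed true
landscape (a single energy realization); chimeras and their outcomes are
sampled on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .alignment import LibraryDesign, ParentAlignment
from .contacts import ContactMap, ContactStateTable, classify_states
from .evidence import FunctionalDataset
from .field import EnergyRealization, RandomFieldParams, sample_energy_realization
from .landscape import sample_random_alignment, sample_random_crossovers

#: default synthetic scale: large enough for identifiability, small enough
#: for seconds-scale pipelines
DEFAULT_M = 120
DEFAULT_CONTACT_DENSITY = 0.042  # ~300 contacts at M = 120


def synth_contact_map(
    M: int,
    mode: str = "random_pairs",
    density_or_radius: float = DEFAULT_CONTACT_DENSITY,
    seed: int = 0,
) -> ContactMap:
    """Random contact map: uniform pairs, or geometric locality.

    ``random_pairs`` draws round(density * M(M-1)/2) column pairs
    uniformly without replacement. ``geometric`` grows a self-avoiding
    random walk on the cubic lattice (greedy unvisited-neighbor steps,
    restarting when trapped) and thresholds pairwise Euclidean distance at
    *density_or_radius* lattice units, enriching small |i - j| pairs the
    way chain connectivity does in real folds.
    """
    rng = np.random.default_rng(seed)
    if mode == "random_pairs":
        density = density_or_radius
        if not 0.0 <= density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        n_pairs = M * (M - 1) // 2
        n_pick = round(density * n_pairs)
        idx = rng.choice(n_pairs, size=n_pick, replace=False)
        pairs = [
            (i + 1, j + 1)
            for i in range(M)
            for j in range(i + 1, M)
        ]
        chosen = sorted(pairs[x] for x in idx)
        return ContactMap(length=M, contacts=tuple(chosen))
    if mode == "geometric":
        coords = _self_avoiding_walk(M, rng)
        radius = density_or_radius
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        ii, jj = np.where(np.triu(d2 <= radius * radius, k=1))
        return ContactMap(
            length=M,
            contacts=tuple((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)),
        )
    raise ValueError(f"unknown mode {mode!r}")


_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _self_avoiding_walk(M: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy self-avoiding walk on Z^3; restarts when trapped."""
    for _ in range(10_000):
        pos = (0, 0, 0)
        visited = {pos}
        path = [pos]
        ok = True
        for _ in range(M - 1):
            options = [
                tuple(np.array(pos) + s)
                for s in _STEPS
            ]
            options = [o for o in options if o not in visited]
            if not options:
                ok = False
                break
            pos = options[rng.integers(len(options))]
            visited.add(pos)
            path.append(pos)
        if ok:
            return np.array(path, dtype=float)
    raise RuntimeError("self-avoiding walk kept trapping; try another seed")


def synth_functional_dataset(
    table: ContactStateTable,
    params: RandomFieldParams,
    n_records: int,
    seed: int,
) -> tuple[pd.DataFrame, EnergyRealization]:
    """Chimeras drawn uniformly without replacement; T ~ Bernoulli(sigma(-E))
    on one fixed landscape realization.
    """
    if n_records < 1:
        raise ValueError("need at least one record")
    if n_records > table.n_chimeras:
        raise ValueError("more records requested than library members")
    ss = np.random.SeedSequence(seed)
    s_real, s_draw = (s.generate_state(1)[0] >> 1 for s in ss.spawn(2))
    realization = sample_energy_realization(table, params, int(s_real))
    rng = np.random.default_rng(int(s_draw))
    rows = rng.choice(table.n_chimeras, size=n_records, replace=False)
    probs = expit(-realization.energies[rows])
    T = (rng.random(n_records) < probs).astype(int)
    return (
        pd.DataFrame(
            {"chimera": [table.codes[r] for r in rows], "functional": T}
        ),
        realization,
    )


def synth_property_dataset(
    design: LibraryDesign,
    p: int,
    additive_sd: float,
    epistatic_sd: float,
    noise_sd: float,
    n: int,
    seed: int,
) -> tuple[pd.DataFrame, float]:
    """Block-additive + cross-block-epistatic + noise property records.

    Per-block parent effects are N(0, additive_sd^2); for every block pair
    a p-by-p interaction table is drawn N(0, epistatic_sd^2) and
    double-centered so it is orthogonal to the additive part on the
    balanced factorial. Returns (records, true additivity), where the true
    additivity is the realized additive variance over the realized total
    variance (noise variance included).
    """
    if min(additive_sd, epistatic_sd, noise_sd) < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    B = design.n_blocks
    add = rng.normal(0.0, additive_sd, size=(B, p))
    add -= add.mean(axis=1, keepdims=True)
    inter = {}
    for b1 in range(B):
        for b2 in range(b1 + 1, B):
            tab = rng.normal(0.0, epistatic_sd, size=(p, p))
            tab -= tab.mean(axis=0, keepdims=True)
            tab -= tab.mean(axis=1, keepdims=True)
            inter[(b1, b2)] = tab
    v_add = float(sum((add[b] ** 2).mean() for b in range(B)))
    v_epi = float(sum((t**2).mean() for t in inter.values()))
    denom = v_add + v_epi + noise_sd**2
    true_additivity = 1.0 if denom == 0 else v_add / denom

    assign = rng.integers(1, p + 1, size=(n, B))
    values = add[np.arange(B), assign - 1].sum(axis=1)
    for (b1, b2), tab in inter.items():
        values = values + tab[assign[:, b1] - 1, assign[:, b2] - 1]
    values = values + rng.normal(0.0, noise_sd, size=n)
    codes = ["".join(str(u) for u in a) for a in assign]
    return (
        pd.DataFrame({"chimera": codes, "value": values}),
        true_additivity,
    )


@dataclass
class SyntheticSystem:
    """A complete seeded system: every field regenerates bit-identically."""

    alignment: ParentAlignment
    contact_map: ContactMap
    design: LibraryDesign
    table: ContactStateTable
    true_params: RandomFieldParams
    realization: EnergyRealization
    functional: pd.DataFrame
    seed: int


DEFAULT_TRUE_PARAMS = RandomFieldParams(
    mu_P=-0.3, var_P=0.5, mu_N=2.0, var_N=1.0
)


def make_system(
    seed: int,
    M: int = DEFAULT_M,
    p: int = 3,
    n_crossovers: int = 7,
    identity: float = 0.7,
    contact_density: float = DEFAULT_CONTACT_DENSITY,
    params: RandomFieldParams = DEFAULT_TRUE_PARAMS,
    n_records: int = 2000,
) -> SyntheticSystem:
    """One complete synthetic recombination system from a single seed."""
    ss = np.random.SeedSequence(seed)
    s_aln, s_map, s_des, s_fun = (
        int(s.generate_state(1)[0] >> 1) for s in ss.spawn(4)
    )
    alignment = sample_random_alignment(M, p, identity, s_aln)
    contact_map = synth_contact_map(M, "random_pairs", contact_density, s_map)
    design = sample_random_crossovers(M, n_crossovers, seed=s_des)
    table = classify_states(alignment, design, contact_map)
    functional, realization = synth_functional_dataset(
        table, params, n_records, s_fun
    )
    return SyntheticSystem(
        alignment=alignment,
        contact_map=contact_map,
        design=design,
        table=table,
        true_params=params,
        realization=realization,
        functional=functional,
        seed=seed,
    )


def functional_dataset_from_frame(df: pd.DataFrame) -> FunctionalDataset:
    return FunctionalDataset.from_frame(df)
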