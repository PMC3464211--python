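"""Residue contact maps and parental/novel classification of contact states.

A contact is an unordered pair of alignment columns whose residues touch in
the folded structure (any two heavy atoms within a distance cutoff). Across
a combinatorial chimera library, each contact can realize several distinct
residue pairs ("states"): a state is *parental* (P) if some single parent
carries exactly that residue pair at those two columns, and *novel* (N)
otherwise. Novel states arise only when a contact spans blocks donated by
different parents at nonconserved positions; the number of novel states a
chimera carries is its SCHEMA disruption n_c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    GAP,
    Chimera,
    LibraryDesign,
    ParentAlignment,
    enumerate_assignments,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactMap:
    """Consensus set of contacting alignment-column pairs (1-based, i < j)."""

    length: int
    contacts: tuple[tuple[int, int], ...]
    support: tuple[float, ...] = ()
    n_chains: int = 0

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"invalid contact ({i}, {j}) for M={self.length}")
        if self.support and len(self.support) != len(self.contacts):
            raise ValueError("support length mismatch")

    @property
    def k(self) -> int:
        return len(self.contacts)


@dataclass
class ContactStateTable:
    """Per-contact enumeration of residue-pair states over a full library.

    Attributes
    ----------
    contacts : contact column pairs (1-based)
    state_slices : per-contact (start, stop) into the global state axis
    state_residues : residue pair of each global state
    is_novel : bool array over global states (True = novel)
    codes : chimera code per library row, lexicographic order
    assignments : (L, B) 1-based parent assignment per chimera
    state_of : (L, k) global state index realized by each chimera at each contact
    """

    alignment: ParentAlignment
    design: LibraryDesign
    contacts: tuple[tuple[int, int], ...]
    state_slices: list[tuple[int, int]]
    state_residues: list[tuple[str, str]]
    is_novel: np.ndarray
    codes: list[str]
    assignments: np.ndarray
    state_of: np.ndarray

    @property
    def k(self) -> int:
        """Total number of contacts."""
        return len(self.contacts)

    @property
    def n_states(self) -> int:
        return len(self.is_novel)

    @property
    def n_chimeras(self) -> int:
        return len(self.codes)

    @property
    def n_c(self) -> np.ndarray:
        """SCHEMA disruption (novel-state count) per chimera."""
        return self.is_novel[self.state_of].sum(axis=1)

    def row_index(self, code: str) -> int:
        p, B = self.alignment.n_parents, self.design.n_blocks
        idx = 0
        for ch in code:
            idx = idx * p + (int(ch) - 1)
        return idx

    def indicator_matrix(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Binary chimera-by-state matrix X; each row sums to k."""
        st = self.state_of if rows is None else self.state_of[rows]
        X = np.zeros((st.shape[0], self.n_states), dtype=np.int8)
        r = np.repeat(np.arange(st.shape[0]), st.shape[1])
        X[r, st.ravel()] = 1
        return X

    def state_occupancy(self) -> np.ndarray:
        """Fraction of library chimeras realizing each global state."""
        counts = np.bincount(self.state_of.ravel(), minlength=self.n_states)
        return counts / self.n_chimeras

    def design_matrix_for(
        self, codes: list[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(X, is_novel) restricted to the states realized by *codes*.

        Columns are the distinct states realized by at least one of the
        given chimeras, in global state order.
        """
        rows = np.array([self.row_index(c) for c in codes])
        st = self.state_of[rows]
        used = np.unique(st)
        remap = np.full(self.n_states, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        X = np.zeros((len(rows), len(used)), dtype=np.int8)
        r = np.repeat(np.arange(len(rows)), st.shape[1])
        X[r, remap[st].ravel()] = 1
        return X, self.is_novel[used].copy()


def classify_states(
    alignment: ParentAlignment,
    design: LibraryDesign,
    contact_map: ContactMap,
) -> ContactStateTable:
    """Enumerate and label the residue-pair states of every contact.

    For contact (i, j) the realizable states are the distinct residue pairs
    (parent u residue at i, parent v residue at j) over block assignments;
    when i and j fall in the same block, u = v. A state is parental iff some
    parent carries exactly that pair. Contacts touching a column gapped in
    any parent are excluded (the model assigns gaps no energy semantics);
    the exclusion count is logged.
    """
    if contact_map.length != alignment.length:
        raise ValueError("contact map and alignment length differ")
    arr = alignment.as_array()
    p = alignment.n_parents
    block_of = design.block_of_column()

    kept: list[tuple[int, int]] = []
    n_gap_dropped = 0
    for i, j in contact_map.contacts:
        if GAP in arr[:, i - 1] or GAP in arr[:, j - 1]:
            n_gap_dropped += 1
        else:
            kept.append((i, j))
    if n_gap_dropped:
        logger.warning(
            "excluded %d contact(s) touching a gapped column", n_gap_dropped
        )

    assignments = enumerate_assignments(p, design.n_blocks)
    L = assignments.shape[0]
    state_slices: list[tuple[int, int]] = []
    state_residues: list[tuple[str, str]] = []
    novel_flags: list[bool] = []
    state_of = np.empty((L, len(kept)), dtype=np.int64)

    offset = 0
    for t, (i, j) in enumerate(kept):
        bi, bj = block_of[i - 1], block_of[j - 1]
        res_i, res_j = arr[:, i - 1], arr[:, j - 1]
        parent_pairs = {(res_i[u], res_j[u]) for u in range(p)}
        # distinct states and a (u, v) -> local state lookup
        pair_to_local: dict[tuple[str, str], int] = {}
        uv_state = np.empty((p, p), dtype=np.int64)
        for u in range(p):
            for v in range(p):
                if bi == bj and u != v:
                    uv_state[u, v] = -1
                    continue
                pair = (res_i[u], res_j[v])
                if pair not in pair_to_local:
                    pair_to_local[pair] = len(pair_to_local)
                    state_residues.append(pair)
                    novel_flags.append(pair not in parent_pairs)
                uv_state[u, v] = pair_to_local[pair]
        n_local = len(pair_to_local)
        state_slices.append((offset, offset + n_local))
        state_of[:, t] = (
            uv_state[assignments[:, bi] - 1, assignments[:, bj] - 1] + offset
        )
        offset += n_local

    codes = ["".join(str(u) for u in a) for a in assignments]
    return ContactStateTable(
        alignment=alignment,
        design=design,
        contacts=tuple(kept),
        state_slices=state_slices,
        state_residues=state_residues,
        is_novel=np.array(novel_flags, dtype=bool),
        codes=codes,
        assignments=assignments,
        state_of=state_of,
    )


def schema_disruption(table: ContactStateTable) -> tuple[np.ndarray, float]:
    """Per-chimera novel-contact counts n_c and the library mean <n_c>."""
    n_c = table.n_c
    return n_c, float(n_c.mean())


def classify_sequence_contacts(
    sequence: str, alignment: ParentAlignment, contact_map: ContactMap
) -> tuple[int, int]:
    """(parental, novel) contact counts of an arbitrary aligned sequence.

    A contact's realized residue pair is parental iff some parent carries
    exactly that pair at those columns — the rule used for simulated random
    and homologous substitutions, where sequences need not lie in any
    recombination library. Gapped contacts are excluded as in
    :func:`classify_states`.
    """
    if len(sequence) != alignment.length:
        raise ValueError("sequence length mismatch")
    arr = alignment.as_array()
    n_par = n_nov = 0
    for i, j in contact_map.contacts:
        col_i, col_j = arr[:, i - 1], arr[:, j - 1]
        if GAP in col_i or GAP in col_j:
            continue
        pair = (sequence[i - 1], sequence[j - 1])
        if any(
            (col_i[u], col_j[u]) == pair for u in range(alignment.n_parents)
        ):
            n_par += 1
        else:
            n_nov += 1
    return n_par, n_nov
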