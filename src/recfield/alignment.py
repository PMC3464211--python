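"""Parent alignments, crossover designs, and combinatorial chimera libraries.

A recombination library is defined by ``p`` aligned parent sequences and
``n`` crossover positions that partition the alignment into ``B = n + 1``
contiguous blocks. A chimera is an assignment of one parent to each block;
its code is the digit string of (1-based) parent indices, leftmost digit =
N-terminal block, matching the naming convention used for published SCHEMA
libraries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = set(AMINO_ACIDS) | {GAP}

#: refuse to enumerate libraries larger than this (protects memory)
DEFAULT_ENUMERATION_CAP = 10**6


class LibraryTooLargeError(ValueError):
    """Raised when a full factorial library exceeds the enumeration cap."""


@dataclass(frozen=True)
class ParentAlignment:
    """Gapped, equal-length parent sequences over the 20 amino acids + gap.

    Columns are indexed 1-based in all public interfaces and file formats.
    """

    parent_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 parents")
        if len(self.parent_ids) != len(self.rows):
            raise ValueError("parent_ids and rows length mismatch")
        m = len(self.rows[0])
        for pid, row in zip(self.parent_ids, self.rows):
            if len(row) != m:
                raise ValueError(
                    f"parent {pid!r} has length {len(row)}, expected {m}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise ValueError(f"parent {pid!r} has illegal symbols {bad}")

    @property
    def n_parents(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def residues_at(self, column: int) -> tuple[str, ...]:
        """Parent residues at a 1-based alignment column."""
        return tuple(row[column - 1] for row in self.rows)

    def conserved(self, column: int) -> bool:
        """True iff all parents carry the same non-gap residue at *column*."""
        res = set(self.residues_at(column))
        return len(res) == 1 and GAP not in res

    def as_array(self) -> np.ndarray:
        """(p, M) array of single-character residue codes."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def pairwise_identity(self) -> dict[tuple[int, int], float]:
        """Fraction of identical columns for every parent pair (1-based keys)."""
        arr = self.as_array()
        out = {}
        for a, b in itertools.combinations(range(self.n_parents), 2):
            out[(a + 1, b + 1)] = float(np.mean(arr[a] == arr[b]))
        return out


@dataclass(frozen=True)
class LibraryDesign:
    """Crossover positions partitioning an alignment of length M into blocks.

    Each crossover is recorded as the 1-based column index of the *last*
    column of a block; ``n`` crossovers give ``B = n + 1`` blocks.
    """

    length: int
    crossovers: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        xs = self.crossovers
        if list(xs) != sorted(set(xs)):
            raise ValueError("crossovers must be strictly increasing")
        if xs and (xs[0] < 1 or xs[-1] >= self.length):
            raise ValueError("crossovers must satisfy 1 <= x < M")

    @property
    def n_crossovers(self) -> int:
        return len(self.crossovers)

    @property
    def n_blocks(self) -> int:
        return len(self.crossovers) + 1

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        """Blocks as (first, last) 1-based inclusive column ranges."""
        edges = (0,) + self.crossovers + (self.length,)
        return tuple(
            (edges[b] + 1, edges[b + 1]) for b in range(self.n_blocks)
        )

    def block_of_column(self) -> np.ndarray:
        """(M,) array mapping 0-based column index -> 0-based block index."""
        out = np.empty(self.length, dtype=np.int64)
        for b, (lo, hi) in enumerate(self.blocks):
            out[lo - 1 : hi] = b
        return out


@dataclass(frozen=True)
class Chimera:
    """A block-to-parent assignment; ``code`` digit k assigns block k."""

    assignment: tuple[int, ...]  # 1-based parent index per block

    @property
    def code(self) -> str:
        return "".join(str(u) for u in self.assignment)

    @classmethod
    def from_code(cls, code: str) -> "Chimera":
        return cls(tuple(int(ch) for ch in code))


def enumerate_library(
    alignment: ParentAlignment,
    design: LibraryDesign,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[Chimera]:
    """All p^B chimeras of the full factorial library, in lexicographic code order.

    Raises :class:`LibraryTooLargeError` above *cap*; sample instead of
    enumerating in that case.
    """
    p, B = alignment.n_parents, design.n_blocks
    size = p**B
    if size > cap:
        raise LibraryTooLargeError(
            f"library has {size} chimeras (> cap {cap}); "
            "use uniform sampling operations instead of enumeration"
        )
    return [
        Chimera(a) for a in itertools.product(range(1, p + 1), repeat=B)
    ]


def enumerate_assignments(p: int, n_blocks: int) -> np.ndarray:
    """(p^B, B) int array of 1-based assignments in lexicographic order."""
    grids = np.meshgrid(*[np.arange(1, p + 1)] * n_blocks, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def chimera_sequence(
    chimera: Chimera, alignment: ParentAlignment, design: LibraryDesign
) -> str:
    """Splice the gapped chimera sequence: column i carries the residue of the
    parent assigned to the block containing i."""
    if len(chimera.assignment) != design.n_blocks:
        raise ValueError("assignment length does not match block count")
    parts = []
    for (lo, hi), u in zip(design.blocks, chimera.assignment):
        parts.append(alignment.rows[u - 1][lo - 1 : hi])
    return "".join(parts)


def substitutions_to_closest_parent(
    sequence: str, alignment: ParentAlignment
) -> int:
    """Minimum Hamming distance from *sequence* to any parent row.

    Gaps count as an ordinary 21st symbol.
    """
    if len(sequence) != alignment.length:
        raise ValueError(
            f"sequence length {len(sequence)} != alignment length "
            f"{alignment.length}"
        )
    return min(
        sum(a != b for a, b in zip(sequence, row)) for row in alignment.rows
    )
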