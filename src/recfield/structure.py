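"""Building consensus contact maps from PDB coordinates.

Many structures are usually available for a protein family; the consensus
contact map retains a column pair iff the mapped residues touch (any two
heavy atoms within a distance cutoff, default 4.5 Å) in strictly more than
a consensus fraction (default 50%) of the usable chains. Chains are mapped
onto alignment columns through a deterministic global alignment to their
best-identity parent, and chains below a minimum identity to every parent
are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1

from .alignment import GAP, ParentAlignment
from .contacts import ContactMap

logger = logging.getLogger(__name__)


@dataclass
class ChainMapping:
    """Result of aligning a structure chain onto alignment columns."""

    parent_index: int  # 1-based best parent
    identity: float  # matches / aligned non-gap positions
    columns: dict[int, int]  # 0-based chain residue index -> 1-based column


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def map_chain_to_alignment(
    chain_sequence: str, alignment: ParentAlignment
) -> ChainMapping:
    """Map chain residues to alignment columns via the best-identity parent.

    The chain is globally aligned (BLOSUM62, gap open -11 / extend -1,
    first optimal alignment) to each ungapped parent; the best parent by
    identity wins, ties broken by parent order. Chain residues paired with
    parent residues inherit that parent's alignment column; inserted
    residues stay unmapped.
    """
    if not chain_sequence:
        raise ValueError("empty chain sequence")
    aligner = _make_aligner()
    best: tuple[float, int, object, list[int]] | None = None
    for pi, row in enumerate(alignment.rows):
        ungapped = row.replace(GAP, "")
        # 1-based alignment column of each ungapped parent residue
        cols = [c + 1 for c, ch in enumerate(row) if ch != GAP]
        aln = aligner.align(chain_sequence, ungapped)[0]
        matches = aligned = 0
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            aligned += qe - qs
            matches += sum(
                chain_sequence[qs + o] == ungapped[ts + o]
                for o in range(qe - qs)
            )
        identity = matches / aligned if aligned else 0.0
        if best is None or identity > best[0]:
            best = (identity, pi, aln, cols)
    identity, pi, aln, cols = best
    columns: dict[int, int] = {}
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for o in range(qe - qs):
            columns[qs + o] = cols[ts + o]
    return ChainMapping(parent_index=pi + 1, identity=identity, columns=columns)


def _chain_residues(chain) -> tuple[str, list]:
    """One-letter sequence and residue objects of the standard amino acids."""
    seq, residues = [], []
    for res in chain.get_residues():
        if not is_aa(res, standard=True):
            continue
        seq.append(protein_letters_3to1[res.get_resname()])
        residues.append(res)
    return "".join(seq), residues


def _heavy_atom_coords(residue) -> np.ndarray:
    """Heavy-atom coordinates; disordered atoms resolve to highest occupancy."""
    coords = []
    for atom in residue.get_unpacked_list():
        if atom.element == "H":
            continue
        coords.append(atom.get_coord())
    # collapse altlocs: keep the highest-occupancy copy of each atom name
    byname: dict[str, tuple[float, np.ndarray]] = {}
    for atom in residue.get_unpacked_list():
        if atom.element == "H":
            continue
        occ = atom.get_occupancy() or 0.0
        if atom.get_name() not in byname or occ > byname[atom.get_name()][0]:
            byname[atom.get_name()] = (occ, atom.get_coord())
    return np.array([c for _, c in byname.values()], dtype=float)


def chain_contacts(
    residues: list, mapping: ChainMapping, distance: float
) -> set[tuple[int, int]]:
    """Column pairs (i < j) with any heavy atoms within *distance* Å."""
    mapped = [
        (mapping.columns[idx], _heavy_atom_coords(res))
        for idx, res in enumerate(residues)
        if idx in mapping.columns
    ]
    out: set[tuple[int, int]] = set()
    for a in range(len(mapped)):
        ca, xa = mapped[a]
        for b in range(a + 1, len(mapped)):
            cb, xb = mapped[b]
            if ca == cb:
                continue
            d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)
            if d2.min() <= distance * distance:
                out.add((min(ca, cb), max(ca, cb)))
    return out


def build_contact_map(
    structure_paths: list[str],
    alignment: ParentAlignment,
    distance: float = 4.5,
    consensus: float = 0.5,
    min_chain_identity: float = 0.5,
    min_separation: int = 0,
) -> ContactMap:
    """Consensus contact map from one or more PDB files.

    Every protein chain of the first model of each file is considered;
    chains below *min_chain_identity* to every parent are discarded. A
    column pair is retained iff it is contacting in strictly more than
    *consensus* of the usable chains. Pairs with |i - j| < *min_separation*
    are dropped.
    """
    parser = PDBParser(QUIET=True)
    per_chain: list[set[tuple[int, int]]] = []
    for path in structure_paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", path)
        model = next(structure.get_models())
        for chain in model.get_chains():
            seq, residues = _chain_residues(chain)
            if not seq:
                continue
            try:
                mapping = map_chain_to_alignment(seq, alignment)
            except Exception as exc:  # unmappable chain: skip, keep going
                logger.warning("skipping chain %s: %s", chain.id, exc)
                continue
            if mapping.identity < min_chain_identity:
                logger.warning(
                    "chain %s identity %.2f below threshold %.2f; discarded",
                    chain.id,
                    mapping.identity,
                    min_chain_identity,
                )
                continue
            per_chain.append(chain_contacts(residues, mapping, distance))
    if not per_chain:
        raise ValueError("no chain passed the identity filter")
    counts: dict[tuple[int, int], int] = {}
    for contacts in per_chain:
        for pair in contacts:
            counts[pair] = counts.get(pair, 0) + 1
    n = len(per_chain)
    kept = sorted(
        pair
        for pair, c in counts.items()
        if c / n > consensus and abs(pair[1] - pair[0]) >= min_separation
    )
    return ContactMap(
        length=alignment.length,
        contacts=tuple(kept),
        support=tuple(counts[pair] / n for pair in kept),
        n_chains=n,
    )
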