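"""Shared fixtures: the hand-checkable two-parent system and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from recfield import (
    ContactMap,
    LibraryDesign,
    ParentAlignment,
    RandomFieldParams,
    classify_states,
)


@pytest.fixture(scope="session")
def tiny():
    """Two parents ACDE/AGDF, one crossover after column 2, three contacts.

    Small enough that every state, energy, and covariance can be checked
    by hand: contact (2,3) has two parental states, (2,4) two parental and
    two novel, (3,4) two parental; chimeras 12 and 21 each carry one novel
    contact.
    """
    aln = ParentAlignment(("p1", "p2"), ("ACDE", "AGDF"))
    design = LibraryDesign(length=4, crossovers=(2,))
    cmap = ContactMap(length=4, contacts=((2, 3), (2, 4), (3, 4)))
    table = classify_states(aln, design, cmap)
    return aln, design, cmap, table


@pytest.fixture(scope="session")
def tiny_params():
    return RandomFieldParams(mu_P=-1.0, var_P=0.5, mu_N=3.0, var_N=1.0)


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element,
                  occupancy=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00"
        f"          {element:>2s}"
    )


def write_ca_pdb(path, sequence, coords, chain="A"):
    """Minimal single-chain PDB with one CA atom per residue."""
    from Bio.Data.IUPACData import protein_letters_1to3

    lines = []
    for idx, (aa, (x, y, z)) in enumerate(zip(sequence, coords), start=1):
        lines.append(
            pdb_atom_line(
                idx, "CA", protein_letters_1to3[aa].upper(), chain, idx,
                x, y, z, "C"
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
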