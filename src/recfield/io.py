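"""Readers and writers for the package's file formats.

All serialized coordinates are 1-based alignment columns. Formats: gapped
FASTA for alignments, TSV (columns i, j, support) for contact maps, YAML
for crossover designs, CSV for chimera datasets, JSON for field
parameters.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import LibraryDesign, ParentAlignment
from .contacts import ContactMap
from .field import RandomFieldParams


def read_alignment(path: str | Path) -> ParentAlignment:
    """Gapped FASTA -> ParentAlignment; case-normalized, order-preserving."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need at least 2 FASTA records")
    rows = [str(r.seq).upper() for r in records]
    m = len(rows[0])
    for rec, row in zip(records, rows):
        if len(row) != m:
            raise ValueError(
                f"{path}: record {rec.id!r} has length {len(row)}, "
                f"expected {m}"
            )
    return ParentAlignment(
        parent_ids=tuple(r.id for r in records), rows=tuple(rows)
    )


def write_alignment(alignment: ParentAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=pid, description="")
        for pid, row in zip(alignment.parent_ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_contact_map(path: str | Path, length: int | None = None) -> ContactMap:
    """TSV with header columns i, j and optional support (defaults 1.0)."""
    df = pd.read_csv(path, sep="\t")
    if "i" not in df.columns or "j" not in df.columns:
        raise ValueError(f"{path}: expected header columns 'i' and 'j'")
    if (df["i"] >= df["j"]).any():
        raise ValueError(f"{path}: contacts must satisfy i < j")
    support = (
        tuple(float(s) for s in df["support"])
        if "support" in df.columns
        else tuple(1.0 for _ in range(len(df)))
    )
    m = int(df["j"].max()) if length is None else length
    return ContactMap(
        length=m,
        contacts=tuple(
            (int(i), int(j)) for i, j in zip(df["i"], df["j"])
        ),
        support=support,
    )


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    support = cmap.support or tuple(1.0 for _ in cmap.contacts)
    df = pd.DataFrame(
        {
            "i": [i for i, _ in cmap.contacts],
            "j": [j for _, j in cmap.contacts],
            "support": support,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> LibraryDesign:
    """YAML with fields name, length, crossovers (1-based)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return LibraryDesign(
        length=int(d["length"]),
        crossovers=tuple(int(x) for x in d.get("crossovers", [])),
        name=str(d.get("name", "")),
    )


def write_design(design: LibraryDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "name": design.name,
                "length": design.length,
                "crossovers": list(design.crossovers),
            },
            fh,
            sort_keys=False,
        )


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Chimera dataset CSV: columns chimera, functional, optional value."""
    df = pd.read_csv(path, dtype={"chimera": str})
    if "chimera" not in df.columns:
        raise ValueError(f"{path}: missing 'chimera' column")
    return df


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_params(path: str | Path) -> RandomFieldParams:
    return RandomFieldParams.from_json(Path(path).read_text())


def write_params(params: RandomFieldParams, path: str | Path) -> None:
    Path(path).write_text(params.to_json() + "\n")
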