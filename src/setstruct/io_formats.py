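"""Readers and writers for the external formats the pipeline touches.

FASTA (sequences and alignments), Newick (trees) and TSV (tabular reports).
Every other module consumes and produces the types defined here; no other
module opens a sequence file directly.

Conventions: residues are stored uppercase; the only gap character is ``-``
(``.`` on input is normalized); FASTA output wraps at 60 characters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
GAP = "-"

_WRAP = 60


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, illegal residues)."""


class AlignmentFormatError(ValueError):
    """Raised when aligned FASTA rows have unequal lengths."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single ungapped sequence with a declared alphabet."""

    id: str
    residues: str
    alphabet: str = "dna"  # "dna" | "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record has an empty id")
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has empty residues")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise FastaFormatError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentBlock:
    """An alignment: ordered (id, gapped residue string) rows of equal length."""

    rows: tuple[tuple[str, str], ...]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(seq) for _, seq in self.rows}
            if len(lengths) > 1:
                raise AlignmentFormatError(
                    f"ragged alignment rows: lengths {sorted(lengths)}"
                )
        ids = [rid for rid, _ in self.rows]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate row ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def ungapped(self, rid: str) -> SequenceRecord:
        return SequenceRecord(
            id=rid, residues=self.row(rid).replace(GAP, ""), alphabet=self.alphabet
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP).replace("–", GAP)


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Residues are uppercased; duplicate ids or residues outside the declared
    alphabet raise :class:`FastaFormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalize(str(rec.seq)),
                alphabet=alphabet,
                description=desc,
            )
        )
    return records


def read_fasta_map(path: str | Path, alphabet: str = "dna") -> dict[str, SequenceRecord]:
    """FASTA as an id -> record mapping (order preserved by dict semantics)."""
    return {rec.id: rec for rec in read_fasta(path, alphabet)}


def read_alignment(path: str | Path, alphabet: str = "protein") -> AlignmentBlock:
    """Read an aligned FASTA file; rows must be equal length."""
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AlignmentFormatError(f"duplicate row id {rec.id!r}")
        seen.add(rec.id)
        rows.append((rec.id, _normalize(str(rec.seq))))
    block = AlignmentBlock(rows=tuple(rows), alphabet=alphabet)
    # validate residues via ungapping
    for rid, _ in block.rows:
        block.ungapped(rid)
    return block


def write_fasta(
    records: Iterable[SequenceRecord] | AlignmentBlock, path: str | Path
) -> None:
    """Write sequences or an alignment as FASTA, wrapped at 60 columns."""
    if isinstance(records, AlignmentBlock):
        items: Sequence[tuple[str, str]] = records.rows
    else:
        items = [(r.id, r.residues) for r in records]
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i:i + _WRAP] + "\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (phylo_nj.Tree or Newick string) to a file.

    Branch lengths are printed to 6 significant digits and bootstrap supports
    as integer internal-node labels; output round-trips through dendropy.
    """
    if hasattr(tree, "to_newick"):
        newick = tree.to_newick()
    else:
        newick = str(tree).strip()
        if not newick.endswith(";"):
            newick += ";"
    Path(path).write_text(newick + "\n")


def write_table(rows: Sequence[Mapping], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as a TSV with a header row.

    Column order is taken from ``columns`` or from the first record's key
    order; an empty row list with explicit columns yields a header-only file.
    """
    if columns is None:
        if not rows:
            raise ValueError("write_table needs columns when rows are empty")
        columns = list(rows[0].keys())
    buf = io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for row in rows:
        buf.write("\t".join(str(row[c]) for c in columns) + "\n")
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_table` back into string records."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:] if ln]
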