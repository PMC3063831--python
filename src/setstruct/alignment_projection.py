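"""Codon-alignment back-translation and intron-position projection.

A protein alignment of the conserved regions is back-translated to a codon
alignment (each residue replaced by its codon, each gap by ``---``), then
every gene's intron CDS offsets are projected into alignment coordinates.
Intron positions are compared under a strict identity rule: two introns are
the same character state only when they fall on exactly the same nucleotide
alignment column — positions apart by even one base pair are non-identical.
Shared positions are the structural synapomorphies used to group paralogs;
near-identical positions ("intron sliding") are reported separately and
never merged.

Position convention: a projected intron is addressed by the 1-based
nucleotide alignment column of the last exonic base 5' of the intron. Every
report header states this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from setstruct.io_formats import GAP, AlignmentBlock, SequenceRecord
from setstruct.gene_structure import GeneStructure

POSITION_CONVENTION = (
    "intron position = 1-based nucleotide alignment column of the last "
    "exonic base 5' of the intron"
)


class BacktranslationError(ValueError):
    """CDS/protein-row inconsistency during back-translation."""


class ProjectionError(ValueError):
    """Gene missing from the alignment or inconsistent with its row."""


@dataclass(frozen=True)
class CodonAlignment:
    """Nucleotide alignment obtained by expanding a protein alignment 3x."""

    rows: tuple[tuple[str, str], ...]
    source_protein_alignment: AlignmentBlock

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
        raise ProjectionError(f"gene {rid!r} absent from codon alignment")


@dataclass(frozen=True)
class ProjectedIntron:
    gene_id: str
    alignment_column: int  # 1-based, last exonic base before the intron
    phase: int
    cds_offset: int


@dataclass(frozen=True)
class IntronIncidenceMatrix:
    """Gene x alignment-column incidence of introns, with phases.

    ``cells[(gene_id, column)]`` holds the phase of that gene's intron at that
    column; absent keys mean no intron. Rows of intronless genes are present
    in ``genes`` but have no cells.
    """

    genes: tuple[str, ...]
    columns: tuple[int, ...]
    cells: Mapping[tuple[str, int], int]

    def phase_at(self, gene_id: str, column: int) -> int | None:
        return self.cells.get((gene_id, column))

    def genes_at(self, column: int) -> list[str]:
        return [g for g in self.genes if (g, column) in self.cells]

    def intron_count(self, gene_id: str) -> int:
        return sum(1 for (g, _c) in self.cells if g == gene_id)


def backtranslate_alignment(
    protein_alignment: AlignmentBlock,
    cds_by_id: Mapping[str, SequenceRecord],
) -> CodonAlignment:
    """Expand a protein alignment to codons using each gene's CDS.

    The CDS must be exactly 3x the ungapped residue count, optionally plus
    one stop codon (which is trimmed). Each codon is verified to translate to
    its aligned residue (``X`` in the protein row accepts any codon).
    """
    out_rows: list[tuple[str, str]] = []
    for rid, gapped in protein_alignment.rows:
        if rid not in cds_by_id:
            raise BacktranslationError(f"no CDS provided for {rid!r}")
        cds = cds_by_id[rid].residues
        n_res = sum(1 for ch in gapped if ch != GAP)
        if len(cds) == 3 * n_res + 3:
            cds = cds[:-3]  # trailing stop codon
        elif len(cds) != 3 * n_res:
            raise BacktranslationError(
                f"{rid}: CDS length {len(cds_by_id[rid].residues)} does not "
                f"match {n_res} aligned residues (expected {3 * n_res} or "
                f"{3 * n_res + 3} nt)"
            )
        codons = iter(cds[k:k + 3] for k in range(0, len(cds), 3))
        parts: list[str] = []
        for col, res in enumerate(gapped, start=1):
            if res == GAP:
                parts.append(GAP * 3)
                continue
            codon = next(codons)
            if res != "X" and "N" not in codon:
                trans = str(Seq(codon).translate())
                if trans != res:
                    raise BacktranslationError(
                        f"{rid}: codon {codon} at protein column {col} "
                        f"translates to {trans}, aligned residue is {res}"
                    )
            parts.append(codon)
        out_rows.append((rid, "".join(parts)))
    return CodonAlignment(
        rows=tuple(out_rows), source_protein_alignment=protein_alignment
    )


def _aligned_region_offset(row_ungapped: str, cds: str, gene_id: str) -> int:
    """CDS offset at which the aligned (sub)sequence starts.

    The alignment may cover only the conserved part of the CDS; the aligned
    nucleotides must occur contiguously in the CDS.
    """
    start = cds.find(row_ungapped)
    if start == -1:
        raise ProjectionError(
            f"{gene_id}: aligned nucleotides are not a contiguous "
            "subsequence of the CDS"
        )
    # if the subsequence occurs more than once, the leftmost placement is used
    return start


def project_introns(
    structure: GeneStructure,
    codon_alignment: CodonAlignment,
    cds: SequenceRecord | None = None,
) -> tuple[list[ProjectedIntron], list[dict]]:
    """Map a gene's intron CDS offsets into codon-alignment columns.

    Returns ``(projected, out_of_region)``: introns whose offset falls inside
    the aligned CDS sub-interval become :class:`ProjectedIntron`; the rest
    are returned as dicts (never silently dropped).
    """
    row = codon_alignment.row(structure.gene_id)
    ungapped = row.replace(GAP, "")
    if cds is not None:
        region_start = _aligned_region_offset(ungapped, cds.residues,
                                              structure.gene_id)
    else:
        region_start = 0
    region_end = region_start + len(ungapped)

    # map: ungapped index -> 1-based alignment column
    col_of_ungapped: list[int] = [
        k + 1 for k, ch in enumerate(row) if ch != GAP
    ]

    projected: list[ProjectedIntron] = []
    out_of_region: list[dict] = []
    for it in structure.introns:
        # offset counts bases 5' of the intron; needs >=1 exonic base on each
        # side inside the region for the column to exist
        if region_start < it.cds_offset < region_end:
            local = it.cds_offset - region_start  # bases of the region 5' of intron
            column = col_of_ungapped[local - 1]
            projected.append(
                ProjectedIntron(
                    gene_id=structure.gene_id,
                    alignment_column=column,
                    phase=it.phase,
                    cds_offset=it.cds_offset,
                )
            )
        else:
            out_of_region.append({
                "gene_id": structure.gene_id,
                "cds_offset": it.cds_offset,
                "phase": it.phase,
                "reason": "outside aligned region",
            })
    return projected, out_of_region


def build_incidence_matrix(
    projections: Iterable[ProjectedIntron],
    gene_ids: Iterable[str],
) -> IntronIncidenceMatrix:
    """Assemble projections into a gene x column incidence matrix.

    ``gene_ids`` must list every analyzed gene so that intronless genes keep
    an (all-absent) row.
    """
    genes = tuple(gene_ids)
    cells: dict[tuple[str, int], int] = {}
    for p in projections:
        if p.gene_id not in genes:
            raise ProjectionError(f"projection for unknown gene {p.gene_id!r}")
        key = (p.gene_id, p.alignment_column)
        if key in cells and cells[key] != p.phase:
            raise ProjectionError(
                f"conflicting phases at {key}: {cells[key]} vs {p.phase}"
            )
        cells[key] = p.phase
    columns = tuple(sorted({c for _, c in cells}))
    return IntronIncidenceMatrix(genes=genes, columns=columns, cells=cells)


def shared_intron_positions(matrix: IntronIncidenceMatrix) -> list[dict]:
    """Columns occupied by two or more genes — candidate synapomorphies.

    Grouping uses exact column equality only (no tolerance window); each
    entry records the member genes, their phases, and whether all phases
    agree (they must if the codon alignment is consistent).
    """
    shared: list[dict] = []
    for col in matrix.columns:
        members = matrix.genes_at(col)
        if len(members) < 2:
            continue
        phases = [matrix.cells[(g, col)] for g in members]
        shared.append({
            "alignment_column": col,
            "gene_ids": members,
            "phases": phases,
            "phase_agreement": len(set(phases)) == 1,
        })
    return shared


def assign_structural_groups(
    matrix: IntronIncidenceMatrix, min_shared: int = 2
) -> dict[str, list[str]]:
    """Partition genes by shared intron positions (single linkage).

    Two genes link when they share at least ``min_shared`` identical intron
    positions. Genes with zero introns form the distinguished ``intronless``
    class. Groups are numbered ``G1, G2, ...`` by their smallest member id.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    intronless = [g for g in matrix.genes if matrix.intron_count(g) == 0]
    with_introns = [g for g in matrix.genes if g not in intronless]

    cols_of = {
        g: {c for (gg, c) in matrix.cells if gg == g} for g in with_introns
    }
    parent = {g: g for g in with_introns}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a_i, a in enumerate(with_introns):
        for b in with_introns[a_i + 1:]:
            if len(cols_of[a] & cols_of[b]) >= min_shared:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for g in with_introns:
        clusters.setdefault(find(g), []).append(g)
    ordered = sorted(clusters.values(), key=lambda ms: min(ms))
    groups = {f"G{k + 1}": sorted(ms) for k, ms in enumerate(ordered)}
    if intronless:
        groups["intronless"] = sorted(intronless)
    return groups


def sliding_candidates(
    matrix: IntronIncidenceMatrix, window: int = 6
) -> list[dict]:
    """Pairs of distinct occupied columns within ``window`` nt of each other.

    Candidate intron-sliding events: reported for inspection, never merged
    into shared positions.
    """
    out: list[dict] = []
    cols = matrix.columns
    for i, c1 in enumerate(cols):
        for c2 in cols[i + 1:]:
            if 0 < c2 - c1 <= window:
                out.append({
                    "column_a": c1,
                    "column_b": c2,
                    "distance_nt": c2 - c1,
                    "genes_a": matrix.genes_at(c1),
                    "genes_b": matrix.genes_at(c2),
                })
    return out


def incidence_rows(matrix: IntronIncidenceMatrix) -> list[dict]:
    """Matrix as TSV-ready rows: phase digit per occupied cell, '.' otherwise."""
    rows = []
    for g in matrix.genes:
        row: dict = {"gene_id": g}
        for c in matrix.columns:
            ph = matrix.phase_at(g, c)
            row[f"col{c}"] = "." if ph is None else str(ph)
        rows.append(row)
    return rows
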