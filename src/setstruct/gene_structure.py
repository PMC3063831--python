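"""Exon/intron structure inference from paired mRNA (CDS) and genomic sequences.

The genomic sequence of a gene is modelled as an alternation
``exon_1 intron_1 exon_2 ... intron_{k-1} exon_k`` whose concatenated exons
reproduce the mRNA (the CDS including the stop codon; UTRs are unsupported).
Exons are indel-free relative to the mRNA: every mRNA base maps to exactly one
genomic base, so inference reduces to choosing intron placements.

The optimization is a spliced-alignment dynamic program over
(genomic prefix, mRNA prefix) with two layers (last operation was a match /
last operation closed an intron). Decompositions are ranked by

1. number of non-canonical (not GT..AG) introns, minimized;
2. number of exonic substitutions (mismatches), minimized;
3. leftmost intron placement (ties broken toward the smallest genomic donor
   coordinates).

This is a deterministic stand-in for spliced-alignment tools followed by
manual inspection of splice consensus signals: when a junction repeat makes
several placements equivalent, the canonical GT..AG placement with the
leftmost donor is always selected.

Coordinates are 0-based half-open internally; reports print 1-based values.
Intron phase is the CDS offset modulo 3: phase 0 lies between codons, phase 1
after the first base of a codon, phase 2 after the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from setstruct.io_formats import SequenceRecord

_INF = np.int64(1) << 40


class NoAlignmentError(ValueError):
    """No exon/intron decomposition exists within the mismatch budget."""


class StructurePreconditionError(ValueError):
    """Input violates a precondition (e.g. mRNA longer than genomic)."""


@dataclass(frozen=True)
class StructureParams:
    """Tuning knobs for structure inference.

    max_mismatches: exonic substitution budget (0 suits simulated data where
        exons are copied verbatim; raise for real, independently sequenced
        pairs).
    min_intron: shortest intron considered (nt). Real spliceosomal introns
        are >=~60 nt; 4 is the logical floor (two splice dinucleotides).
    require_gt_ag: when True, non-GT..AG introns are forbidden rather than
        merely penalized and warned about.
    """

    max_mismatches: int = 0
    min_intron: int = 4
    require_gt_ag: bool = False


@dataclass(frozen=True)
class ExonBlock:
    genomic_start: int
    genomic_end: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (self.genomic_end - self.genomic_start
                == self.cds_end - self.cds_start > 0):
            raise ValueError(f"inconsistent exon block {self}")

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass(frozen=True)
class IntronRecord:
    """One intron: its genomic span, CDS offset, phase and splice dinucleotides.

    ``cds_offset`` counts the mRNA nucleotides 5' of the intron; ``phase`` is
    ``cds_offset % 3``.
    """

    cds_offset: int
    phase: int
    genomic_start: int
    genomic_end: int
    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        if self.cds_offset <= 0:
            raise ValueError("cds_offset must be positive")
        if self.phase != self.cds_offset % 3:
            raise ValueError("phase must equal cds_offset mod 3")

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start

    @property
    def canonical(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"


@dataclass(frozen=True)
class GeneStructure:
    gene_id: str
    exons: tuple[ExonBlock, ...]
    introns: tuple[IntronRecord, ...]
    mrna_length: int

    def __post_init__(self) -> None:
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if sum(e.length for e in self.exons) != self.mrna_length:
            raise ValueError("exon lengths must sum to mRNA length")

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def phases(self) -> tuple[int, ...]:
        return tuple(i.phase for i in self.introns)

    def cds_offsets(self) -> tuple[int, ...]:
        return tuple(i.cds_offset for i in self.introns)

    def splice(self, genomic: str) -> str:
        """Concatenate the exon substrings of ``genomic`` (the inferred mRNA)."""
        return "".join(genomic[e.genomic_start:e.genomic_end] for e in self.exons)


def compute_phase(cds_offset: int) -> int:
    """Intron phase from its CDS offset: 0 between codons, 1/2 within."""
    if cds_offset <= 0:
        raise StructurePreconditionError(
            f"cds_offset must be a positive integer, got {cds_offset}"
        )
    return cds_offset % 3


def _mismatch_row(g_arr: np.ndarray, m_base: str) -> np.ndarray:
    # N in either sequence never counts as a mismatch
    if m_base == "N":
        return np.zeros(len(g_arr), dtype=np.int64)
    return ((g_arr != m_base) & (g_arr != "N")).astype(np.int64)


def _spliced_dp(
    g: str, m: str, min_intron: int, require_gt_ag: bool, big: int,
    swap_priority: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill the two DP layers.

    Cost encoding: ``big * primary + secondary`` where (primary, secondary) is
    (non-canonical introns, mismatches), or the reverse when
    ``swap_priority`` is set.
    """
    N, M = len(g), len(m)
    g_arr = np.frombuffer(g.encode(), dtype="S1").astype("U1")

    donor_gt = np.zeros(N + 1, dtype=bool)
    acc_ag = np.zeros(N + 1, dtype=bool)
    for i in range(N - 1):
        if g[i] == "G" and g[i + 1] == "T":
            donor_gt[i] = True
    for i in range(2, N + 1):
        if g[i - 2] == "A" and g[i - 1] == "G":
            acc_ag[i] = True

    noncanon_pen = np.int64(1 if swap_priority else big)

    dp_m = np.full((N + 1, M + 1), _INF, dtype=np.int64)
    dp_i = np.full((N + 1, M + 1), _INF, dtype=np.int64)
    dp_m[0, 0] = 0

    mm_scale = np.int64(big if swap_priority else 1)

    for j in range(1, M + 1):
        mm = _mismatch_row(g_arr, m[j - 1]) * mm_scale
        prev = np.minimum(dp_m[:-1, j - 1], dp_i[:-1, j - 1])
        dp_m[1:, j] = prev + mm

        # intron arrivals: donor at i', acceptor ends at i, i - i' >= min_intron
        base = dp_m[:, j]
        base_gt = np.where(donor_gt, base, _INF)
        pref_gt = np.minimum.accumulate(base_gt)
        col = np.full(N + 1, _INF, dtype=np.int64)
        if N >= min_intron:
            sl = slice(min_intron, N + 1)
            shifted_gt = pref_gt[:-min_intron]
            cand = np.where(acc_ag[sl], shifted_gt, shifted_gt + noncanon_pen
                            if not require_gt_ag else _INF)
            if not require_gt_ag:
                pref_all = np.minimum.accumulate(base)
                cand = np.minimum(cand, pref_all[:-min_intron] + noncanon_pen)
            col[sl] = np.minimum(col[sl], cand)
        dp_i[:, j] = np.minimum(dp_i[:, j], col)

    return dp_m, dp_i


def _traceback(
    g: str, m: str, dp_m: np.ndarray, dp_i: np.ndarray,
    min_intron: int, require_gt_ag: bool, big: int, swap_priority: bool,
) -> list[tuple[int, int, int]]:
    """Recover intron placements (genomic_start, genomic_end, cds_offset).

    Tie rule: prefer continuing the exon (match predecessor) over closing an
    intron, and for each intron the smallest feasible donor coordinate —
    together this yields the leftmost placement among equally scored
    decompositions.
    """
    mm_scale = big if swap_priority else 1
    noncanon_pen = 1 if swap_priority else big
    introns: list[tuple[int, int, int]] = []
    i, j, layer = len(g), len(m), "m"
    while i > 0 or j > 0:
        if layer == "m":
            gb, mb = g[i - 1], m[j - 1]
            mm = 0 if (gb == mb or gb == "N" or mb == "N") else mm_scale
            target = dp_m[i, j] - mm
            if dp_m[i - 1, j - 1] == target:
                layer = "m"
            elif dp_i[i - 1, j - 1] == target:
                layer = "i"
            else:  # pragma: no cover - internal consistency
                raise RuntimeError("traceback failed in match layer")
            i, j = i - 1, j - 1
        else:
            acc_ok = i >= 2 and g[i - 2:i] == "AG"
            found = False
            for i2 in range(1, i - min_intron + 1):
                donor_ok = g[i2:i2 + 2] == "GT"
                canonical = donor_ok and acc_ok
                if require_gt_ag and not canonical:
                    continue
                pen = 0 if canonical else noncanon_pen
                if dp_m[i2, j] + pen == dp_i[i, j]:
                    introns.append((i2, i, j))
                    i, layer, found = i2, "m", True
                    break
            if not found:  # pragma: no cover - internal consistency
                raise RuntimeError("traceback failed in intron layer")
    introns.reverse()
    return introns


def _build_structure(
    gene_id: str, g: str, m: str, placements: list[tuple[int, int, int]]
) -> GeneStructure:
    exons: list[ExonBlock] = []
    introns: list[IntronRecord] = []
    g_pos = cds_pos = 0
    for gs, ge, off in placements:
        exons.append(ExonBlock(g_pos, gs, cds_pos, off))
        introns.append(
            IntronRecord(
                cds_offset=off,
                phase=off % 3,
                genomic_start=gs,
                genomic_end=ge,
                donor=g[gs:gs + 2],
                acceptor=g[ge - 2:ge],
            )
        )
        g_pos, cds_pos = ge, off
    exons.append(ExonBlock(g_pos, len(g), cds_pos, len(m)))
    return GeneStructure(
        gene_id=gene_id, exons=tuple(exons), introns=tuple(introns),
        mrna_length=len(m),
    )


def infer_structure(
    genomic: SequenceRecord,
    mrna: SequenceRecord,
    params: StructureParams = StructureParams(),
) -> GeneStructure:
    """Infer the exon/intron decomposition of ``genomic`` that yields ``mrna``.

    Returns the unique optimal :class:`GeneStructure` under the ranking
    (fewest non-canonical introns, fewest mismatches, leftmost placement).
    If that optimum exceeds ``max_mismatches``, a second pass prioritizing
    mismatches over splice-site canonicality is attempted before giving up.

    Raises :class:`NoAlignmentError` when no decomposition fits the budget and
    :class:`StructurePreconditionError` on invalid input.
    """
    if genomic.alphabet != "dna" or mrna.alphabet != "dna":
        raise StructurePreconditionError("both sequences must be DNA")
    g, m = genomic.residues, mrna.residues
    if len(m) > len(g):
        raise StructurePreconditionError(
            f"mRNA ({len(m)} nt) longer than genomic ({len(g)} nt) "
            f"for {mrna.id!r}"
        )
    big = len(m) + len(g) + 2  # exceeds any mismatch or intron count

    for swap in (False, True):
        dp_m, dp_i = _spliced_dp(g, m, params.min_intron,
                                 params.require_gt_ag, big, swap)
        best = int(dp_m[len(g), len(m)])
        if best >= _INF:
            break
        if swap:
            mismatches, noncanon = divmod(best, big)
        else:
            noncanon, mismatches = divmod(best, big)
        if mismatches <= params.max_mismatches:
            placements = _traceback(g, m, dp_m, dp_i, params.min_intron,
                                    params.require_gt_ag, big, swap)
            structure = _build_structure(genomic.id, g, m, placements)
            if noncanon and not params.require_gt_ag:
                bad = [k for k, it in enumerate(structure.introns)
                       if not it.canonical]
                warnings.warn(
                    f"{genomic.id}: {len(bad)} non-GT..AG intron(s) at "
                    f"index(es) {bad}", stacklevel=2)
            return structure
        if params.require_gt_ag:
            break  # priorities coincide when non-canonical introns are barred
    raise NoAlignmentError(
        f"{genomic.id}: no exon/intron decomposition reproduces the mRNA "
        f"within {params.max_mismatches} mismatch(es)"
    )


def splice_report(structure: GeneStructure) -> list[dict]:
    """Per-intron splice-signal audit: donor/acceptor dinucleotides and
    whether they are canonical GT..AG."""
    return [
        {
            "intron_index": k,
            "donor": it.donor,
            "acceptor": it.acceptor,
            "canonical": it.canonical,
        }
        for k, it in enumerate(structure.introns)
    ]


def structure_rows(structure: GeneStructure) -> list[dict]:
    """Flatten a GeneStructure for TSV output (1-based inclusive coordinates)."""
    rows = []
    for k, e in enumerate(structure.exons):
        rows.append({
            "gene_id": structure.gene_id, "feature": "exon", "index": k,
            "genomic_start": e.genomic_start + 1, "genomic_end": e.genomic_end,
            "cds_offset": "", "phase": "", "donor": "", "acceptor": "",
        })
    for k, it in enumerate(structure.introns):
        rows.append({
            "gene_id": structure.gene_id, "feature": "intron", "index": k,
            "genomic_start": it.genomic_start + 1, "genomic_end": it.genomic_end,
            "cds_offset": it.cds_offset, "phase": it.phase,
            "donor": it.donor, "acceptor": it.acceptor,
        })
    return rows
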