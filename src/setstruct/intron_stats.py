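"""Per-group intron phase statistics.

For each group of genes: intron counts by phase (0/1/2), the total, the mean
number of introns per gene, and phase percentages, plus a grand-total row.
Rounding is half-up: one decimal for means, nearest integer for percentages
(so 208/24 prints 8.7 and 125/208 prints 60%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from setstruct.gene_structure import GeneStructure

ORPHAN_LABEL = "Orphan"
TOTAL_LABEL = "Total"


def _half_up(value: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupPhaseStats:
    group_label: str
    n_genes: int
    phase_counts: tuple[int, int, int]
    total_introns: int
    mean_per_gene: float | None  # half-up to 1 decimal; None when no genes
    phase_percent: tuple[int, int, int] | None  # None when no introns

    @property
    def mean_str(self) -> str:
        return "—" if self.mean_per_gene is None else f"{self.mean_per_gene:g}"


def _stats_row(label: str, n_genes: int, counts: Sequence[int]) -> GroupPhaseStats:
    n0, n1, n2 = (int(c) for c in counts)
    total = n0 + n1 + n2
    mean = _half_up(total / n_genes, 1) if n_genes > 0 else None
    pct = (
        tuple(int(_half_up(100 * c / total, 0)) for c in (n0, n1, n2))
        if total > 0 else None
    )
    return GroupPhaseStats(
        group_label=label, n_genes=n_genes, phase_counts=(n0, n1, n2),
        total_introns=total, mean_per_gene=mean, phase_percent=pct,
    )


def tabulate_phase_stats(
    structures: Iterable[GeneStructure],
    groups: Mapping[str, str] | None = None,
) -> list[GroupPhaseStats]:
    """Tabulate intron counts by phase per group, with a grand-total row.

    Groups appear in first-seen order of their genes; genes without a label
    fall into ``Orphan``. Empty input yields a single zero Total row.
    """
    groups = groups or {}
    order: list[str] = []
    per_group: dict[str, list[int]] = {}
    genes_in_group: dict[str, int] = {}
    for s in structures:
        label = groups.get(s.gene_id, ORPHAN_LABEL)
        if label not in per_group:
            order.append(label)
            per_group[label] = [0, 0, 0]
            genes_in_group[label] = 0
        genes_in_group[label] += 1
        for ph in s.phases():
            per_group[label][ph] += 1

    rows = [
        _stats_row(label, genes_in_group[label], per_group[label])
        for label in order
    ]
    total_counts = [sum(r.phase_counts[k] for r in rows) for k in range(3)]
    rows.append(
        _stats_row(TOTAL_LABEL, sum(r.n_genes for r in rows), total_counts)
    )
    return rows


def aggregate_counts(
    group_rows: Sequence[tuple[str, int, tuple[int, int, int]]]
) -> list[GroupPhaseStats]:
    """Build the same table directly from per-group phase-count rows
    ``(label, n_genes, (n0, n1, n2))`` — for re-aggregating published counts."""
    rows = [_stats_row(label, n, counts) for label, n, counts in group_rows]
    total_counts = [sum(r.phase_counts[k] for r in rows) for k in range(3)]
    rows.append(
        _stats_row(TOTAL_LABEL, sum(r.n_genes for r in rows), total_counts)
    )
    return rows


def max_min_summary(structures: Sequence[GeneStructure]) -> dict:
    """Extreme intron counts with every gene attaining them."""
    if not structures:
        raise ValueError("max_min_summary requires at least one gene")
    counts = {s.gene_id: s.n_introns for s in structures}
    lo, hi = min(counts.values()), max(counts.values())
    return {
        "min": (lo, sorted(g for g, c in counts.items() if c == lo)),
        "max": (hi, sorted(g for g, c in counts.items() if c == hi)),
    }


def flag_reference_discrepancies(
    computed: Sequence[GroupPhaseStats],
    reference: Mapping[str, Mapping[str, float]],
) -> list[dict]:
    """Compare computed rows against externally published cell values.

    ``reference`` maps group label -> {field: published value} where field is
    one of ``mean_per_gene``, ``phase0_percent``, ``phase1_percent``,
    ``phase2_percent``, ``total_introns``. Returns one record per cell that
    disagrees with the computed value — published tables occasionally carry
    rounding slips, and those cells should be flagged rather than matched.
    """
    by_label = {r.group_label: r for r in computed}
    flags: list[dict] = []
    for label, cells in reference.items():
        row = by_label.get(label)
        if row is None:
            flags.append({"group": label, "field": "(row)",
                          "published": "", "computed": "missing"})
            continue
        for fieldname, published in cells.items():
            if fieldname == "mean_per_gene":
                got = row.mean_per_gene
            elif fieldname == "total_introns":
                got = row.total_introns
            elif fieldname.startswith("phase") and fieldname.endswith("_percent"):
                k = int(fieldname[5])
                got = row.phase_percent[k] if row.phase_percent else None
            else:
                raise KeyError(f"unknown reference field {fieldname!r}")
            if got is None or abs(float(got) - float(published)) > 1e-9:
                flags.append({
                    "group": label, "field": fieldname,
                    "published": published, "computed": got,
                })
    return flags


def stats_rows(rows: Sequence[GroupPhaseStats]) -> list[dict]:
    """TSV-ready representation mirroring the published table layout."""
    out = []
    for r in rows:
        pct = r.phase_percent or ("", "", "")
        out.append({
            "group": r.group_label,
            "n_genes": r.n_genes,
            "phase0": r.phase_counts[0], "phase0_pct": pct[0],
            "phase1": r.phase_counts[1], "phase1_pct": pct[1],
            "phase2": r.phase_counts[2], "phase2_pct": pct[2],
            "total_introns": r.total_introns,
            "mean_per_gene": r.mean_str,
        })
    return out
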