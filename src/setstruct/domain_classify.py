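"""Rule-based classification of Su(var)3-9 SET protein domain architectures.

Eligible proteins carry a SET domain plus a PreSET (or its AWS subdomain);
proteins lacking both flanking domains are rejected, mirroring the usual
curation step for this family. Architectures are then classified into five
types and ten subtypes by their N-terminal marker domains:

    A (SRA present, the SUVH hallmark): A1 with AT_hook, A2 with PostSET,
        A3 otherwise;
    B (ZnF_C2H2): B1;
    C (WIYLD): C1 with PostSET, C2 without;
    D (AWS in place of a full PreSET): D1;
    E (no marker): E3 with TPR_1, E1 with PostSET, E2 otherwise.

Rules are applied in that order, so a protein carrying several markers takes
the earliest matching type (e.g. SRA + ZnF_C2H2 is type A). ``XXX`` tokens
mark unannotated stretches and are ignored — they are placeholders, not
evidence of absence. Multiple copies of a domain collapse to presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

DOMAIN_VOCABULARY = {
    "AT_hook", "SRA", "ZnF_C2H2", "WIYLD", "AWS", "TPR_1",
    "PreSET", "SET", "PostSET", "XXX",
}

SUBTYPES = ("A1", "A2", "A3", "B1", "C1", "C2", "D1", "E1", "E2", "E3")

_MARKERS = ("SRA", "ZnF_C2H2", "WIYLD", "AWS", "TPR_1", "AT_hook")


class IneligibleArchitectureError(ValueError):
    """Protein lacks SET, or lacks both PreSET and AWS."""


class UnknownDomainError(ValueError):
    """Domain name outside the controlled vocabulary."""


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered N-to-C domain list of one protein."""

    protein_id: str
    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        for d in self.domains:
            if d not in DOMAIN_VOCABULARY:
                raise UnknownDomainError(
                    f"{self.protein_id}: unknown domain {d!r}"
                )

    def has(self, domain: str) -> bool:
        return domain in self.domains


@dataclass(frozen=True)
class ArchitectureClass:
    type: str     # A..E
    subtype: str  # A1..E3

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES or self.subtype[0] != self.type:
            raise ValueError(f"inconsistent class {self.type}/{self.subtype}")


def classify_architecture(arch: DomainArchitecture) -> ArchitectureClass:
    """Assign the type/subtype of one eligible architecture.

    Raises :class:`IneligibleArchitectureError` for proteins without a SET
    domain or without either PreSET or AWS.
    """
    if not arch.has("SET"):
        raise IneligibleArchitectureError(
            f"{arch.protein_id}: no SET domain"
        )
    if not (arch.has("PreSET") or arch.has("AWS")):
        raise IneligibleArchitectureError(
            f"{arch.protein_id}: neither PreSET nor AWS present"
        )
    _warn_if_marker_not_n_terminal(arch)

    post = arch.has("PostSET")
    if arch.has("SRA"):
        if arch.has("AT_hook"):
            subtype = "A1"
        elif post:
            subtype = "A2"
        else:
            subtype = "A3"
    elif arch.has("ZnF_C2H2"):
        subtype = "B1"
    elif arch.has("WIYLD"):
        subtype = "C1" if post else "C2"
    elif arch.has("AWS") and not arch.has("PreSET"):
        subtype = "D1"
    else:
        if arch.has("TPR_1"):
            subtype = "E3"
        elif post:
            subtype = "E1"
        else:
            subtype = "E2"
    return ArchitectureClass(type=subtype[0], subtype=subtype)


def _warn_if_marker_not_n_terminal(arch: DomainArchitecture) -> None:
    # classification is by presence; a marker C-terminal of SET is legal but
    # unusual enough to surface
    if "SET" not in arch.domains:
        return
    set_idx = arch.domains.index("SET")
    misplaced = [d for d in arch.domains[set_idx + 1:] if d in _MARKERS]
    if misplaced:
        warnings.warn(
            f"{arch.protein_id}: marker domain(s) {misplaced} C-terminal of "
            "SET; classified by presence regardless",
            stacklevel=3,
        )


def type_by_group_table(
    classes: Mapping[str, ArchitectureClass],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Contingency table of subtype counts per phylogenetic group.

    Both maps must cover identical protein ids; all ten subtypes are kept as
    rows (zero cells retained), group columns are sorted.
    """
    missing = set(classes) ^ set(groups)
    if missing:
        raise ValueError(
            f"classification/group id mismatch: {sorted(missing)}"
        )
    group_labels = sorted(set(groups.values()))
    table = pd.DataFrame(
        0, index=list(SUBTYPES), columns=group_labels, dtype=int
    )
    for pid, cls in classes.items():
        table.loc[cls.subtype, groups[pid]] += 1
    return table


def parse_architecture_rows(
    rows: Iterable[Mapping[str, str]]
) -> list[DomainArchitecture]:
    """Build architectures from TSV records with columns
    ``protein_id`` and ``domains`` (comma-separated, N to C)."""
    return [
        DomainArchitecture(
            protein_id=r["protein_id"],
            domains=tuple(d.strip() for d in r["domains"].split(",") if d.strip()),
        )
        for r in rows
    ]
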