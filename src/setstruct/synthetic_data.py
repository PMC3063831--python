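"""Gene-family simulator with known evolutionary history.

A single ancestral gene (CDS split into exons by GT..AG introns) is evolved
down a user-supplied guide tree. Along each branch the simulator applies
point substitutions (uniform nucleotide model at the branch's expected
substitutions/site), intron losses (seamless re-ligation), intron gains
(random-length GT..AG intron at a random CDS offset, rejecting collisions
with existing introns), and retroposition (the mRNA re-inserted into the
genome: every intron of the lineage is removed at once, yielding an
intronless retrogene whose descendants stay intronless unless they regain
introns).

Exons are indel-free, so every gene keeps the same CDS length and the true
protein alignment is the gapless stack of translated CDSs; intron CDS
offsets are constant along lineages, which makes intron homology across the
family exactly recoverable. The four splice dinucleotides of every intron
are immutable, so emitted introns are always GT..AG.

All randomness flows from one ``numpy`` generator fixed by the config seed;
identical configs produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from setstruct.io_formats import AlignmentBlock, SequenceRecord
from setstruct.gene_structure import (
    ExonBlock, GeneStructure, IntronRecord,
)
from setstruct.domain_classify import DomainArchitecture

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class FamilyConfig:
    """Declarative description of one simulated gene family.

    guide_tree: Newick with branch lengths in expected substitutions/site;
        leaf labels are gene ids, internal labels may name branches for
        ``retroposition_branches``.
    ancestral_exon_lengths: exon sizes (nt) of the ancestor; their sum is the
        CDS length (stop codon included) and must be divisible by 3.
    intron_length_range: (min, max) nt for ancestral and gained introns.
    intron_loss_rate / intron_gain_rate: expected events per branch
        (Poisson-distributed counts, independent of branch length).
    retroposition_rate: probability per branch of a retroposition event.
    retroposition_branches: node labels whose subtending branch carries a
        forced retroposition event (for scripted scenarios).
    architectures: optional per-gene domain architectures to emit.
    """

    seed: int
    guide_tree: str
    ancestral_exon_lengths: tuple[int, ...]
    ancestral_intron_positions: tuple[int, ...] | None = None
    intron_length_range: tuple[int, int] = (50, 120)
    intron_loss_rate: float = 0.0
    intron_gain_rate: float = 0.0
    retroposition_rate: float = 0.0
    retroposition_branches: tuple[str, ...] = ()
    intron_loss_branches: tuple[str, ...] = ()
    intron_gain_branches: tuple[str, ...] = ()
    architectures: Mapping[str, tuple[str, ...]] | None = None
    group_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.ancestral_exon_lengths:
            raise ConfigError("need at least one exon")
        if any(e <= 0 for e in self.ancestral_exon_lengths):
            raise ConfigError("exon lengths must be positive")
        if sum(self.ancestral_exon_lengths) % 3 != 0:
            raise ConfigError("CDS length (sum of exons) must be divisible by 3")
        lo, hi = self.intron_length_range
        if not 4 <= lo <= hi:
            raise ConfigError("intron_length_range must satisfy 4 <= min <= max")
        for r in (self.intron_loss_rate, self.intron_gain_rate,
                  self.retroposition_rate):
            if r < 0:
                raise ConfigError("rates must be non-negative")
        derived = self.derived_intron_positions()
        if self.ancestral_intron_positions is not None:
            if tuple(self.ancestral_intron_positions) != derived:
                raise ConfigError(
                    "ancestral_intron_positions inconsistent with exon lengths: "
                    f"expected {derived}"
                )
        cds_len = sum(self.ancestral_exon_lengths)
        if any(not 0 < p < cds_len for p in derived):
            raise ConfigError("intron positions must lie inside the CDS")

    def derived_intron_positions(self) -> tuple[int, ...]:
        pos, acc = [], 0
        for e in self.ancestral_exon_lengths[:-1]:
            acc += e
            pos.append(acc)
        return tuple(pos)


@dataclass
class _GeneState:
    cds: str                      # includes terminal stop codon
    introns: dict[str, tuple[int, str]]  # intron id -> (cds_offset, sequence)


@dataclass(frozen=True)
class TruthRecord:
    """Machine-readable ground truth for one simulated family."""

    structures: Mapping[str, GeneStructure]
    homologous_introns: Mapping[str, Mapping[str, int | None]]  # intron id -> gene -> offset/None
    event_log: tuple[tuple[str, str, str], ...]  # (branch, event, detail)
    protein_alignment: AlignmentBlock
    guide_tree: str


@dataclass(frozen=True)
class SimulatedFamily:
    genomic: tuple[SequenceRecord, ...]
    mrna: tuple[SequenceRecord, ...]
    protein: tuple[SequenceRecord, ...]
    protein_alignment: AlignmentBlock
    architectures: tuple[DomainArchitecture, ...]
    group_labels: Mapping[str, str]
    truth: TruthRecord


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS: sense codons followed by one stop codon."""
    n_codons = length // 3
    codons: list[str] = []
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon in _STOPS:
            continue
        codons.append(codon)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _random_intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    inner = "".join(rng.choice(_BASES, size=length - 4))
    return "GT" + inner + "AG"


def _translate(cds_with_stop: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(cds_with_stop[:-3]).translate())


def _mutate_cds(rng: np.random.Generator, cds: str, p: float) -> str:
    """Substitute CDS sites at probability p, never creating or destroying a
    stop codon (the terminal stop's identity may change, e.g. TAA->TGA)."""
    seq = list(cds)
    n = len(seq)
    hits = np.nonzero(rng.random(n) < p)[0]
    for i in hits:
        old = seq[i]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        codon_start = (i // 3) * 3
        is_terminal = codon_start == n - 3
        for new in choices:
            codon = "".join(seq[codon_start:i]) + new + "".join(seq[i + 1:codon_start + 3])
            if is_terminal:
                if codon in _STOPS:
                    seq[i] = new
                    break
            elif codon not in _STOPS:
                seq[i] = new
                break
    return "".join(seq)


def _mutate_intron(rng: np.random.Generator, intron: str, p: float) -> str:
    # splice dinucleotides (first and last two bases) are immutable
    seq = list(intron)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        if i < 2 or i >= len(seq) - 2:
            continue
        others = [b for b in "ACGT" if b != seq[i]]
        seq[i] = others[rng.integers(0, 3)]
    return "".join(seq)


def _genomic_of(state: _GeneState) -> str:
    parts: list[str] = []
    prev = 0
    for iid, (off, iseq) in sorted(state.introns.items(), key=lambda kv: kv[1][0]):
        parts.append(state.cds[prev:off])
        parts.append(iseq)
        prev = off
    parts.append(state.cds[prev:])
    return "".join(parts)


def _structure_of(gene_id: str, state: _GeneState) -> GeneStructure:
    ordered = sorted(state.introns.values(), key=lambda v: v[0])
    exons: list[ExonBlock] = []
    introns: list[IntronRecord] = []
    g_pos = prev_off = 0
    for off, iseq in ordered:
        exon_len = off - prev_off
        exons.append(ExonBlock(g_pos, g_pos + exon_len, prev_off, off))
        g_pos += exon_len
        introns.append(IntronRecord(
            cds_offset=off, phase=off % 3,
            genomic_start=g_pos, genomic_end=g_pos + len(iseq),
            donor=iseq[:2], acceptor=iseq[-2:],
        ))
        g_pos += len(iseq)
        prev_off = off
    exons.append(ExonBlock(g_pos, g_pos + len(state.cds) - prev_off,
                           prev_off, len(state.cds)))
    return GeneStructure(
        gene_id=gene_id, exons=tuple(exons), introns=tuple(introns),
        mrna_length=len(state.cds),
    )


def simulate_family(config: FamilyConfig) -> SimulatedFamily:
    """Run the simulation and return sequences, alignment and full truth."""
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.guide_tree, schema="newick")

    cds_len = sum(config.ancestral_exon_lengths)
    lo, hi = config.intron_length_range
    ancestral = _GeneState(
        cds=_random_cds(rng, cds_len),
        introns={
            f"anc{k}": (off, _random_intron(rng, lo, hi))
            for k, off in enumerate(config.derived_intron_positions())
        },
    )

    events: list[tuple[str, str, str]] = []
    gain_counter = 0
    leaf_states: dict[str, _GeneState] = {}

    # unnamed internal nodes get deterministic preorder labels so that every
    # event-log entry names its branch unambiguously
    _auto_labels: dict[int, str] = {}
    for k, nd in enumerate(tree.preorder_node_iter()):
        if nd.taxon is None and not nd.label:
            _auto_labels[id(nd)] = f"n{k}"

    def branch_label(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or _auto_labels[id(node)]

    def evolve(node, state: _GeneState) -> None:
        nonlocal gain_counter
        label = branch_label(node)
        blen = node.edge.length or 0.0
        if blen > 0:
            state = _GeneState(
                cds=_mutate_cds(rng, state.cds, blen),
                introns={
                    iid: (off, _mutate_intron(rng, iseq, blen))
                    for iid, (off, iseq) in state.introns.items()
                },
            )
        def lose_one() -> None:
            if not state.introns:
                return
            victim = sorted(state.introns)[rng.integers(0, len(state.introns))]
            off = state.introns[victim][0]
            del state.introns[victim]
            events.append((label, "intron_loss", f"{victim}@{off}"))

        def gain_one() -> None:
            nonlocal gain_counter
            taken = {off for off, _ in state.introns.values()}
            candidates = [p for p in range(1, cds_len) if p not in taken]
            if not candidates:
                return
            off = candidates[rng.integers(0, len(candidates))]
            gain_counter += 1
            iid = f"gain{gain_counter}"
            state.introns[iid] = (off, _random_intron(rng, lo, hi))
            events.append((label, "intron_gain", f"{iid}@{off}"))

        if node.parent_node is not None:  # root branch carries no events
            for _ in range(int(rng.poisson(config.intron_loss_rate))
                           + config.intron_loss_branches.count(label)):
                lose_one()
            for _ in range(int(rng.poisson(config.intron_gain_rate))
                           + config.intron_gain_branches.count(label)):
                gain_one()
            forced = label in config.retroposition_branches
            stochastic = rng.random() < min(config.retroposition_rate, 1.0)
            if (forced or stochastic) and state.introns:
                lost = sorted(state.introns)
                state.introns.clear()
                events.append((label, "retroposition", ",".join(lost)))
        if node.is_leaf():
            leaf_states[label] = state
            return
        for child in node.child_nodes():
            evolve(child, _GeneState(cds=state.cds, introns=dict(state.introns)))

    evolve(tree.seed_node, ancestral)

    gene_ids = tuple(sorted(leaf_states))
    structures = {g: _structure_of(g, leaf_states[g]) for g in gene_ids}
    genomic = tuple(
        SequenceRecord(id=g, residues=_genomic_of(leaf_states[g]), alphabet="dna")
        for g in gene_ids
    )
    mrna = tuple(
        SequenceRecord(id=g, residues=leaf_states[g].cds, alphabet="dna")
        for g in gene_ids
    )
    protein = tuple(
        SequenceRecord(id=g, residues=_translate(leaf_states[g].cds),
                       alphabet="protein")
        for g in gene_ids
    )
    # exons are indel-free: the true alignment is the gapless stack
    alignment = AlignmentBlock(
        rows=tuple((p.id, p.residues) for p in protein), alphabet="protein"
    )

    intron_ids = sorted(
        {iid for st in leaf_states.values() for iid in st.introns}
        | set(ancestral.introns)
    )
    homologous = {
        iid: {
            g: (leaf_states[g].introns[iid][0]
                if iid in leaf_states[g].introns else None)
            for g in gene_ids
        }
        for iid in intron_ids
    }

    arch_map = config.architectures or {}
    default_arch = ("XXX", "SRA", "PreSET", "SET", "PostSET")
    architectures = tuple(
        DomainArchitecture(protein_id=g,
                           domains=tuple(arch_map.get(g, default_arch)))
        for g in gene_ids
    )
    groups = dict(config.group_labels or {})

    truth = TruthRecord(
        structures=structures,
        homologous_introns=homologous,
        event_log=tuple(events),
        protein_alignment=alignment,
        guide_tree=config.guide_tree,
    )
    return SimulatedFamily(
        genomic=genomic, mrna=mrna, protein=protein,
        protein_alignment=alignment, architectures=architectures,
        group_labels=groups, truth=truth,
    )


# ---------------------------------------------------------------------------
# scripted scenario: conserved intron-rich clade, retroposed intronless
# clades, divergent intron-variable clade

_SUVH_TREE = (
    "((((V2a:0.02,V2b:0.02):0.02,(V2c:0.02,(V2d:0.02,V2e:0.02):0.01):0.02)"
    "v2:0.03,((R1a:0.02,R1b:0.02)ra:0.03,(R2a:0.02,R2b:0.02)rb:0.03):0.02)"
    "suvh:0.03,((V6a:0.03,V6b:0.03):0.02,(V6c:0.03,V6d:0.03):0.02)v6:0.03,"
    "(V7a:0.03,V7b:0.03)v7:0.04);"
)

_SUVH_GROUPS = {
    "V2a": "V-2", "V2b": "V-2", "V2c": "V-2", "V2d": "V-2", "V2e": "V-2",
    "R1a": "V-1/3/5", "R1b": "V-1/3/5", "R2a": "V-1/3/5", "R2b": "V-1/3/5",
    "V6a": "V-6", "V6b": "V-6", "V6c": "V-6", "V6d": "V-6",
    "V7a": "V-7", "V7b": "V-7",
}

_SUVH_ARCHS = {
    **{g: ("XXX", "SRA", "PreSET", "SET", "PostSET")
       for g in ("V2a", "V2b", "V2c", "V2d", "V2e",
                 "R1a", "R1b", "R2a", "R2b")},
    **{g: ("WIYLD", "PreSET", "SET", "PostSET")
       for g in ("V6a", "V6b", "V6c", "V6d")},
    **{g: ("ZnF_C2H2", "PreSET", "SET", "PostSET")
       for g in ("V7a", "V7b")},
}


def scenario_suvh(seed: int = 0, **overrides) -> SimulatedFamily:
    """Preset family emulating the qualitative layout of plant SUVH/SUVR
    SET-gene evolution: one structurally conserved intron-rich clade (V-2
    like), two retroposed intronless subclades, a divergent clade with a
    distinct marker domain (V-6 like) and a small outlying clade (V-7 like).

    ``overrides`` replace :class:`FamilyConfig` fields (e.g.
    ``retroposition_branches=()`` disables retroposition).
    """
    config = FamilyConfig(
        seed=seed,
        guide_tree=_SUVH_TREE,
        # cumulative boundaries give phases 1,0,2,0,0,1,0,0 — a phase-0 excess
        # like the one real intron surveys report
        ancestral_exon_lengths=(121, 89, 107, 82, 120, 91, 110, 90, 90),
        intron_length_range=(50, 120),
        intron_loss_rate=0.0,
        intron_gain_rate=0.0,
        retroposition_rate=0.0,
        retroposition_branches=("ra", "rb"),
        intron_loss_branches=("v6", "v6", "v7"),
        intron_gain_branches=("v6", "v7"),
        architectures=_SUVH_ARCHS,
        group_labels=_SUVH_GROUPS,
    )
    if overrides:
        config = replace(config, **overrides)
    return simulate_family(config)
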