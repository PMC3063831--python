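# Methods

## Problem and model

A eukaryotic gene is modelled as an alternation of exons and introns,
`exon_1 intron_1 ... intron_{k-1} exon_k`, whose concatenated exons equal
the mRNA. Here the mRNA is the CDS including the stop codon; UTRs are out of
scope, so "genomic sequence" means the genomic span of the coding region.
Exons are assumed indel-free relative to the mRNA — appropriate for
same-genome cDNA/genomic pairs, where any discrepancy is a sequencing
substitution rather than an alignment indel.

Each intron is summarized by its **CDS offset** `o` (coding nucleotides 5'
of the intron) and **phase** `o mod 3`: phase 0 introns fall between codons,
phase 1 after the first base of a codon, phase 2 after the second. Offsets
use 0-based half-open coordinates internally; reports print 1-based values.

## Structure inference

`infer_structure` is a two-layer dynamic program over (genomic prefix, mRNA
prefix): one layer for states whose last operation consumed a matched exonic
base, one for states whose last operation closed an intron. Intron
transitions are only allowed out of match states, so exons are always
non-empty. The program minimizes the pair

1. number of non-canonical introns (donor/acceptor ≠ GT..AG), then
2. number of exonic substitutions,

encoded lexicographically, with ties broken during traceback toward the
decomposition whose introns sit leftmost in the genome (continue-exon is
preferred over close-intron, and each intron takes the smallest feasible
donor coordinate). This is a deterministic replacement for spliced-alignment
tools followed by manual inspection of splice signals: junction repeats that
make several placements equivalent always resolve to the leftmost canonical
one. If the optimum under this ranking exceeds the mismatch budget, a second
pass swaps the two criteria (fewest mismatches first) before the pair is
declared unalignable — this finds the occasional exact decomposition whose
only defect is a non-canonical splice site.

The per-column recurrences vectorize over the genomic axis (the intron layer
is a running prefix-minimum offset by the minimum intron length), so the
program runs in O(|genomic| × |mRNA|) words; for desk-scale inputs
(≤ 20 kb genomic) this is a few hundred MB at worst and seconds of runtime.

Parameters: `max_mismatches` (default 0 — exact reproduction; raise it for
independently sequenced pairs), `min_intron` (default 4 nt, the logical
floor of two splice dinucleotides; real spliceosomal introns are ≥ ~60 nt),
`require_gt_ag` (default off: non-canonical introns are accepted with a
warning, since curated families contain genuine GC..AG and other variants).

An exhaustive-enumeration oracle (all exon-chain decompositions of small
sequences, ranked by the same criteria) backs the implementation in the test
suite; the two agree on every generated case, including ties.

## Codon alignment and intron projection

`backtranslate_alignment` expands a protein alignment row-by-row: residue →
its codon from the gene's CDS, gap → `---`, trailing stop codon trimmed.
Every codon is checked to translate to its aligned residue, so frame errors
and wrong CDS/row pairings fail loudly with the offending column.

`project_introns` maps an intron to the 1-based nucleotide alignment column
of the last exonic base 5' of the junction. The aligned region may be a
sub-interval of the CDS (conserved domains only); the offset is located by
exact substring search of the ungapped row in the CDS, and introns outside
the region are returned in a separate out-of-region list rather than
dropped. The position convention is stated in every report header, since
numbering conventions differ between publications.

**Shared positions** use strict identity: genes share an intron character
only at exactly equal columns — a one-base offset is a different character.
Phase agreement at a shared column is recorded but not required; with a
consistent codon alignment, equal columns force equal phases, so a
disagreement flags an upstream inconsistency rather than biology. Columns
within a configurable window (default 6 nt) of each other are listed as
intron-sliding candidates for inspection and never merged.

**Structural grouping** is single linkage: two genes link when they share at
least `min_shared` identical positions (default 2 — one shared intron is
weak evidence; set 1 to explore looser groupings). Genes without introns
form a distinguished `intronless` class, the expected signature of
retrogenes; groups are numbered deterministically by smallest member id.

## Phase statistics

`tabulate_phase_stats` counts introns by phase per group (first-seen group
order, unlabeled genes pooled as `Orphan`) and appends a grand-total row.
Rounding is half-up: one decimal for means, nearest integer for
percentages. `flag_reference_discrepancies` compares a computed table to
externally published cell values and reports any disagreement — published
tables occasionally carry cells inconsistent with their own counts (e.g. a
mean of 7.6 where the counts give 7.375 → 7.4, or a 61% where the counts
give 60.1% → 60); such cells are surfaced, not reproduced.

## Domain-architecture typing

Classification is presence-based over a controlled vocabulary and applied in
fixed order: SRA → type A (A1 with AT_hook, A2 with PostSET, A3 otherwise);
else ZnF_C2H2 → B1; else WIYLD → C1/C2 by PostSET; else AWS without
PreSET → D1; else type E (E3 with TPR_1, E1 with PostSET, E2 otherwise).
Eligibility requires a SET domain plus PreSET or AWS; anything else is
rejected, mirroring the curation rule that proteins lacking the PreSET
region are excluded from this family's analysis. `XXX` tokens mark
unannotated stretches and are ignored (placeholders, not absence evidence);
repeated domains collapse to presence; a marker domain C-terminal of SET
triggers a warning but not a reclassification. An exhaustive test over all
presence combinations confirms the rules are total and single-valued.

## Distances, neighbor joining, bootstrap

The distance model is the p-distance with pairwise deletion: per pair,
columns with a gap or ambiguity (X for protein, N for DNA) in either row are
excluded; the distance is mismatches over remaining sites, and a pair with
zero comparable sites is an error naming the pair. The Poisson correction
−ln(1−p) is available as an option; likelihood-based substitution models
(and therefore Γ rate heterogeneity) are out of scope — the p-distance NJ
topology is the reproducible target.

`nj_tree` is the standard Saitou–Nei agglomeration: minimize
Q(a,b) = (m−2)·d(a,b) − r(a) − r(b), join, recompute. Branch lengths follow
the standard formulas; negative lengths are clamped to zero without
redistribution (simplest defensible convention). Ties in Q are broken by the
lexicographically smallest pair of cluster labels, a cluster being labelled
by its smallest leaf — the output is a pure function of the input matrix.
Tests verify the three-taxon analytic lengths, recovery of additive matrices
up to 8 taxa against an exhaustive topology search with least-squares
fitting, and agreement with an independent NJ implementation (scikit-bio).

`bootstrap_support` resamples alignment columns with replacement, rebuilds
distance matrix and NJ tree per replicate, and maps the percentage of
replicates containing each internal bipartition onto the full-data tree
(not a consensus tree). Replicates that produce a zero-overlap pair are
discarded and counted, with a warning above 1% discarded. Support strength
is categorized as weak (50–75%), moderate (76–85%), strong (86–100%);
below 50% is unsupported.

## Synthetic families

The simulator evolves one ancestral gene down a declared guide tree (branch
lengths in expected substitutions/site) and emits every pipeline input plus
truth. Choices, and what they imply:

* **Substitution**: uniform nucleotide model; each site mutates with
  probability equal to the branch length, to one of the three other bases.
  Substitutions never create or destroy a stop codon (the terminal stop may
  change identity), so every emitted CDS translates cleanly. No rate
  heterogeneity, no codon-usage realism.
* **Exons are indel-free**, so all family members keep the same CDS length,
  the true protein alignment is the gapless stack of translations, and
  intron CDS offsets are constant along lineages — intron homology is exact
  and unambiguous. Real conserved domain regions are low-indel but not
  indel-free; passing tests therefore demonstrate correctness of the
  inference/projection machinery, not robustness to alignment error.
* **Intron gain/loss**: Poisson counts per branch at configured expected
  rates (plus forced events on named branches for scripted scenarios); a
  gained intron takes a uniformly random CDS offset, rejecting collisions
  with existing introns, so artificial "sliding" cannot arise. Loss is
  seamless re-ligation.
* **Retroposition** removes every intron of the lineage at the event point,
  as a processed-mRNA reinsertion would.
* **Splice dinucleotides are immutable**, so truth introns are always
  GT..AG; non-canonical splice handling is exercised by hand-built cases
  instead.
* One `numpy` generator seeded from the config drives all randomness;
  identical configs give byte-identical output.

The `scenario_suvh` preset is a 15-gene family on a fixed guide tree with
branch lengths of 0.01–0.04 substitutions/site (within the low-divergence
regime where exact structure recovery is expected): an 8-intron ancestor
(CDS 900 nt — exon boundaries chosen to give a phase-0 excess like real
intron surveys), a five-gene clade that conserves every intron, two
two-gene clades retroposed on their stem branches, and two clades with
forced gains/losses and their own marker domains (WIYLD-type and
ZnF_C2H2-type architectures). These sizes keep the full pipeline, including
bootstraps, in seconds while exercising every code path; they are a
scaled-down emulation of the published 73-protein/24-gene analysis, not a
reproduction of its data.

## Degenerate inputs and numerical conventions

Empty FASTA files parse to empty lists; `N`/`X` never count as mismatches
and are deleted sites in distances; `.` gaps normalize to `-`; Newick branch
lengths print to 6 significant digits with integer supports as internal
labels; empty statistics tables yield a zero Total row with the mean printed
as `—`; the incidence matrix keeps all-absent rows for intronless genes so
they are never silently lost.

## Known limitations

No support for exonic indels, multi-isoform genes, reverse-strand input, or
UTR-containing transcripts; no probabilistic reconstruction of intron
gain/loss on the tree (the grouping is descriptive single linkage); no
maximum-likelihood tree search or model selection; bootstrap supports are
mapped onto the full-data topology only. Domain architectures are inputs —
there is no HMM scanning.
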