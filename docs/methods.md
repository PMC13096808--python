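# Methods

## Geometric frame and conventions

All design arithmetic happens on the non-target strand (the strand carrying
the protospacer and PAM, read 5′→3′). Genomic coordinates are 0-based,
half-open, on the forward strand of the supplied reference; for a '−'-strand
locus the non-target strand is the reverse complement of the reference and
the protospacer start indexes into that strand.

Spacer positions are numbered 1–20 from the PAM-proximal base (21 for the
appended G of a U6-driven 21-nt spacer). The SpCas9-H840A nickase cut sits
3 nt from the PAM, between spacer positions 4 and 3 (`nick_offset = 3`,
configurable). The PBS is numbered from its 5′ (RTT-adjacent) end; PBS
position 1 pairs the nick-adjacent primer base, i.e. spacer position
`nick_offset + 1`.

Two consequences of this register, both load-bearing for the package:

* an unmodified PBS of length *L* is intramolecularly complementary to
  spacer positions `nick_offset+1 … min(20, L+nick_offset)`; with the
  default offset, pairing saturates at *L* = 17 and PBS nucleotides 18–20
  (drawn from the genomic context 5′ of the protospacer) have no spacer
  partner;
* the most PAM-distal spacer position reached by a 7-nt PBS is 10. One
  published description has a 7-nt PBS covering spacer positions 3–10 —
  eight positions for seven nucleotides; with a nick between positions 4
  and 3, seven PBS nucleotides can only cover 4–10, which is the convention
  implemented here (and is consistent with "position 10" as the distal
  bound). `nick_offset` is configurable for anyone preferring another
  register.

Whether long-PBS designs (18–20 nt) draw their extra nucleotides from the
genomic context upstream of the protospacer is assumed here (the only
geometrically coherent option); loci must therefore provide ≥ 25 nt of 5′
context.

## Complementarity map

`complementarity_map` assigns pairs by register and evaluates them
base-by-base: current PBS position *p* with original position *o* (tracked
through deletion provenance) pairs spacer position `o + nick_offset`
whenever that spacer position exists. A deletion of *k* nucleotides
therefore shifts the register of everything 3′ of it by +*k* — the
downstream segment keeps its original partners and a *k*-nt bubble opens in
the spacer (for the default SPELL design, spacer position 16 is unpaired).
`n_paired` counts Watson–Crick pairs only; mismatched positions stay
"covered" but unpaired. The appended 5′ G of a 21-nt spacer is position 21
and is paired exactly when the register reaches it (PBS ≥ 18), computed,
not special-cased.

## RTT and edit encoding

Edits are expressed relative to the nick (`nick_distance` = 1 is the first
nucleotide 3′ of the nick). The RTT is the reverse complement (RNA) of the
first `rtt_length` nucleotides of the *edited* non-target strand 3′ of the
nick, so reverse-transcribing the RTT from the primer reproduces the edited
strand exactly — this round trip is the test oracle for all three edit
types. The default RTT length is `nick_distance − 1 + |alt| + 10`, a modest
10-nt right homology arm; there is no universal RTT rule, so the default is
deliberately simple and overridable.

## Duplex thermodynamics

The PBS:non-target-strand duplex is scored with a two-state
nearest-neighbor model: ΔH/ΔS summed over Watson–Crick stacks plus an
initiation term, entropy salt-corrected as ΔS + 0.368·N·ln[Na⁺]
(SantaLucia's unified correction), Tm = ΔH/(ΔS + R·ln(C_T/4)) and
ΔG(37 °C) = ΔH − 310.15·ΔS. Parameter tables are data, not code
(`data/nn_params.json`): an RNA/DNA hybrid set (Sugimoto et al. 1995,
default) and an RNA/RNA Watson–Crick set (Xia et al. 1998, terminal-AU
penalty omitted). Default conditions: 50 mM monovalent salt, 250 nM total
strand concentration, non-self-complementary duplex; every report records
the table id and conditions. Mismatched positions contribute no stacks
(both flanking stacks are skipped) and are counted in the report — a
deliberately conservative treatment; no mismatch-specific nearest-neighbor
parameters are used. The design report ranks candidates by |Tm − 37 °C|,
following the guideline that a PBS:non-target-strand Tm near 37 °C is
optimal in mammalian cells; the guideline is a ranking hint, not a filter.

## Variant rules

Warnings encode the screen-derived placement rules and are advisory, never
blocking (the screens show exceptions in both directions): spacer
mismatches at PAM-proximal positions (≤ 10) frequently cost editing;
mismatches outside the PBS-complementary region cannot weaken the duplex;
PBS mismatches on short PBSs (≤ 13 nt) mostly reduced editing; SPELL PBS
lengths outside 17–20 draw a warning but are allowed.

Substitution realization: a transition is unique; for transversions the
tie-break picks, of the two candidates, one that is also non-complementary
to the opposing spacer/PBS base, alphabetically first if both qualify. The
published screens list specific mismatch bases per target without a general
rule, so the tie-break is a deterministic package choice with an explicit
alt-base override.

Deletion grids default to starts 6–15 × lengths 1–4 (the screened range);
variants record the intact 5′ segment they are equivalent to, and grid
cells that collapse to an identical PBS (homopolymer runs) are flagged as
duplicates. Combinations apply deletions first, then mismatches, with all
positions interpreted in the original part's coordinates — matching how
combination designs are quoted ("a deletion at position 13 … and a mismatch
at position 15") — and conflicting specs are rejected. PBS-end scrambles
are seeded permutations accepted only if they differ from the original and
leave zero Watson–Crick pairs in the register (bounded rejection sampling,
200 retries).

## Cloning encodings

Golden Gate linkers follow the two-step convention (spacer first between
BpiI sites, RTT-PBS second between BsmBI sites). The 4-nt overhangs are a
documented convention (CACC/AAAC spacer-style defaults) because the cited
backbones do not publish theirs — verify against your plasmid. In-silico
assembly (the round-trip test) reconstructs spacer + scaffold + RTT + PBS
(+ 3′ motif) exactly; inserts containing the step's own recognition site
draw a warning. T7 template primers are promoter + the first 20 DNA-encoded
nucleotides of the pegRNA, with a warning when the first transcribed base
is not G.

## Read simulator

The simulator emulates the read classes the quantifier must distinguish:
unedited, intended-edit, nick-proximal indel classes (offset, type, length,
fraction — each optionally stacked on the edited sequence), with class
counts made exact by largest-remainder rounding and uniform substitution
errors on top. Reads are single-end, full-amplicon (truncatable), constant
Q37, bit-identical per seed. By default errors are never placed inside the
edit ± flank window of intended-edit reads, so zero-error recovery is exact
and classifier correctness is separated from error robustness (a flag
lifts this). Not modeled, hence not demonstrated by passing tests: PCR
amplification bias, chimeric template switching (demultiplexing is instead
tested with fixtures built from two references), position-dependent quality,
paired-end structure, and alignment ambiguity of real indel spectra beyond
the simulated classes.

## Quantification

Alignment is global with affine gaps (defaults: match +2, mismatch −3,
open −8, extend −1); reads below 70% identity are flagged unaligned and
excluded, and aligned reads are the denominator. Equal-length reads whose
gap-free identity already clears the threshold skip the dynamic program — a
pure optimization with identical calls for substitution-only reads; pass
`fast_path=False` to force the DP everywhere. Pre-aligned SAM can be
supplied instead.

Indels count when their reference span intersects the closed
±`indel_window` (default 2) interval around any nick site — the overlap
reading, chosen as the more conservative of "overlaps" vs "starts within";
insertions carry the between-base coordinate of their insertion point.
Intended edits are exact string occurrences of the edited allele with
`edit_window_flank` (default 5) matching reference nucleotides on each
side; a sequencing error inside a flank defeats detection by design
(strict flanks). For substitution edits, the edit percentage counts
intended-edit reads without a window indel; for insertion/deletion edits
all intended-edit reads count and the indel background excludes them.
Untransfected-control percentages are subtracted as-is (negative values
are reported with a flag, never floored), and transfection normalization
divides the background-subtracted edit percentage by the per-sample
efficiency — subtraction-then-division order is fixed and documented.
Whether "total reads" should include reads truncated short of the edit
window is not externally specified; here every aligned read counts.

Demultiplexing assigns a read to the gene whose *both* motifs match within
their windows; reads carrying motifs of different genes (template-switch
chimeras, mispriming) or incomplete motif pairs are excluded with a
reason, and assignment plus exclusion always partition the input.

## Aggregation

pegRNA ids carrying conflicting efficiency values for the same replicate
slot are removed entirely (exact duplicates collapse); what distinguishes
conflicts from legitimate replicates is the replicate column, the only
workable rule when the upstream replicate structure is unspecified.
Summaries report n/mean/SD per construct type × editor × PBS length, with
an optional NGG-only pre-filter. Fold changes divide replicate means (not
per-replicate ratios), matching heatmap normalization, with a near-zero
control flag. Only Welch's two-sided t-test ships; the wider screening
test battery (ANOVA, Kruskal–Wallis, Dunnett, Box–Cox) is routine,
available in standard statistics packages, and intentionally out of scope.

## Problem sizes and determinism

The test suite checks the register against an independent string-level
oracle exhaustively (PBS lengths 1–20 × mismatch positions 1–20 × 100
random loci), round-trips 1,000 random Golden Gate assemblies, audits the
indel window boundary for 1–3-nt indels at offsets −6…+6, verifies exact
truth-table recovery on 10,000 clean reads, and verifies noisy recovery
(error 0.001) within 3 binomial SDs in ≥ 99 of 100 replicates of 50,000
reads — sizes chosen so the whole suite runs in a few minutes on one CPU.
All randomness flows through seeded numpy generators; identical seeds give
bit-identical designs, reads and FASTQ bytes.

## Known limitations

No editing-efficiency prediction (the geometry and thermodynamics inform,
they do not rank targets); no scaffold or 3′-motif secondary-structure
modeling (the epegRNA motif is an opaque configurable sequence); no
RTT-scaffold interaction scoring; no PE3 nicking-sgRNA design; no UMI or
paired-end handling in quantification; nearest-neighbor parameters assume
two-state melting and ignore mismatch-specific and dangling-end terms.
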