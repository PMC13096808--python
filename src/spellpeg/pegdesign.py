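"""pegRNA construction and the spacer:PBS complementarity register.

Geometric frame
---------------
All design arithmetic happens on the **non-target strand** (the strand that
carries the protospacer and PAM, read 5'->3'). For a locus with protospacer
start ``ps``:

* protospacer = non-target[ps : ps+20], PAM = non-target[ps+20 : ps+23];
* spacer position 1 is the PAM-proximal protospacer base (index ``ps+19``),
  position 20 the 5'-most (index ``ps``); a 21G spacer adds position 21 for
  the appended G;
* the SpCas9-H840A nickase cuts the non-target strand 3 nt from the PAM,
  i.e. between spacer positions 4 and 3 (``nick_offset = 3``, configurable);
* the primer is the nicked-strand fragment whose 3' end sits at the nick;
  the PBS (5'->3') is its reverse complement in RNA, so PBS position 1
  (5' end, RTT-adjacent) pairs the nick-adjacent primer base = spacer
  position ``nick_offset + 1``;
* the RTT templates new synthesis for the sequence 3' of the nick
  (spacer positions 3..1, the PAM and beyond), where edits land.

Because the PBS is copied from the protospacer region, an unmodified PBS of
length L is intramolecularly complementary to spacer positions
``nick_offset+1 .. min(20, L+nick_offset)``: with the default offset a PBS
saturates the 20-nt spacer at 17 nt, and PBS nucleotides 18-20 (drawn from
genomic context 5' of the protospacer) gain no spacer partner.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .seqcore import (
    Alphabet,
    DesignError,
    NucSeq,
    SequenceError,
    SubstitutionClass,
    _pam_regex,
    dna,
    revcomp,
    rna,
    to_rna,
)
from .thermo import DEFAULT_THERMO, DuplexReport, ThermoConfig, duplex_tm

#: Canonical SpCas9 sgRNA scaffold (RNA, 76 nt); configurable everywhere.
DEFAULT_SCAFFOLD = rna(
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC"
)

#: Example epegRNA 3' protective pseudoknot motif (tevopreQ1-style). Treated
#: as an opaque configurable sequence; no structure prediction is done.
DEFAULT_END_MOTIF = rna("CGCGGUUCUAUCUAGUUACGCGUUAAACCAACUAGAA")

DEFAULT_NICK_OFFSET = 3
PROTOSPACER_LEN = 20
MIN_UPSTREAM_CONTEXT = 25
MAX_PBS_LEN = 25


class EditType(enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class EditSpec:
    """An intended modification expressed relative to the pegRNA nick.

    ``nick_distance`` is the first edited position counted in nucleotides
    3' of the nick on the non-target strand (1 = the first nucleotide after
    the nick). ``ref_allele`` is empty for insertions, ``alt_allele`` empty
    for deletions.
    """

    edit_type: EditType
    nick_distance: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.nick_distance < 1:
            raise DesignError("nick_distance must be >= 1")
        for allele in (self.ref_allele, self.alt_allele):
            if set(allele) - set("ACGT"):
                raise SequenceError(f"allele must be DNA: {allele!r}")
        t = self.edit_type
        if t is EditType.SUBSTITUTION:
            if not self.ref_allele or len(self.ref_allele) != len(self.alt_allele):
                raise DesignError(
                    "substitution requires equal-length non-empty ref and alt"
                )
        elif t is EditType.INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise DesignError("insertion requires empty ref and non-empty alt")
        elif t is EditType.DELETION:
            if self.alt_allele or not self.ref_allele:
                raise DesignError("deletion requires non-empty ref and empty alt")

    @classmethod
    def substitution(cls, nick_distance: int, ref: str, alt: str) -> "EditSpec":
        return cls(EditType.SUBSTITUTION, nick_distance, ref, alt)

    @classmethod
    def insertion(cls, nick_distance: int, alt: str) -> "EditSpec":
        return cls(EditType.INSERTION, nick_distance, alt_allele=alt)

    @classmethod
    def deletion(cls, nick_distance: int, ref: str) -> "EditSpec":
        return cls(EditType.DELETION, nick_distance, ref_allele=ref)


@dataclass(frozen=True)
class TargetLocus:
    """A reference locus with a fixed protospacer/PAM frame.

    ``reference`` is the forward strand of the amplicon/locus. If
    ``strand`` is '-', the non-target strand is the reverse complement of
    the reference and ``protospacer_start`` indexes into *that* strand
    (5'-most protospacer base, 0-based).
    """

    reference: NucSeq
    protospacer_start: int
    strand: str = "+"
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        if self.reference.alphabet is not Alphabet.DNA:
            raise SequenceError("reference must be DNA")
        if self.strand not in "+-":
            raise DesignError(f"strand must be '+' or '-', got {self.strand!r}")
        ps = self.protospacer_start
        nt = self.nontarget
        if ps < MIN_UPSTREAM_CONTEXT:
            raise DesignError(
                f"reference must extend >= {MIN_UPSTREAM_CONTEXT} nt 5' of the "
                f"protospacer on the non-target strand (have {ps})"
            )
        if ps + PROTOSPACER_LEN + 3 > len(nt):
            raise DesignError("reference too short for protospacer + PAM")
        pam = nt[ps + PROTOSPACER_LEN : ps + PROTOSPACER_LEN + 3]
        if not _pam_regex(self.pam_pattern).fullmatch(pam):
            raise DesignError(
                f"no {self.pam_pattern} PAM at the stated coordinate (found {pam})"
            )

    @property
    def nontarget(self) -> str:
        if self.strand == "+":
            return self.reference.bases
        return revcomp(self.reference).bases

    @property
    def protospacer(self) -> str:
        ps = self.protospacer_start
        return self.nontarget[ps : ps + PROTOSPACER_LEN]

    @property
    def pam(self) -> str:
        ps = self.protospacer_start
        return self.nontarget[ps + PROTOSPACER_LEN : ps + PROTOSPACER_LEN + 3]

    def nick_index(self, nick_offset: int = DEFAULT_NICK_OFFSET) -> int:
        """Between-base nick coordinate on the non-target strand."""
        return self.protospacer_start + PROTOSPACER_LEN - nick_offset

    def spacer_position_base(self, position: int) -> str:
        """Non-target strand base at a spacer position (1 = PAM-proximal)."""
        if not 1 <= position <= PROTOSPACER_LEN:
            raise DesignError(f"spacer position out of range: {position}")
        return self.nontarget[self.protospacer_start + PROTOSPACER_LEN - position]


@dataclass(frozen=True)
class PbsModification:
    """One applied PBS edit, in the coordinates of the originally built PBS."""

    position: int
    kind: str  # 'deletion' | 'mismatch' | 'scramble'
    length: int = 1
    new_base: str = ""


@dataclass(frozen=True)
class SpacerMismatch:
    position: int
    alt_base: str
    substitution_class: SubstitutionClass


@dataclass(frozen=True)
class PegDesign:
    """A fully assembled pegRNA with provenance of applied modifications.

    ``full_sequence`` is always recomputed from the parts, never stored.
    PBS modification positions refer to the originally built PBS (before
    any deletion), which is how variant designs are quoted.
    """

    spacer: NucSeq
    scaffold: NucSeq
    rtt: NucSeq
    pbs: NucSeq
    end_motif: NucSeq | None = None
    has_appended_5prime_G: bool = False
    pbs_modifications: tuple[PbsModification, ...] = ()
    spacer_mismatches: tuple[SpacerMismatch, ...] = ()
    provenance: str = "base"
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("spacer", "scaffold", "rtt", "pbs"):
            part: NucSeq = getattr(self, name)
            if part.alphabet is not Alphabet.RNA:
                raise SequenceError(f"{name} must be RNA")
        if self.end_motif is not None and self.end_motif.alphabet is not Alphabet.RNA:
            raise SequenceError("end_motif must be RNA")
        if not 1 <= len(self.pbs) <= MAX_PBS_LEN:
            raise DesignError(f"PBS length must be in [1, {MAX_PBS_LEN}]")

    @property
    def full_sequence(self) -> NucSeq:
        seq = (
            self.spacer.bases + self.scaffold.bases + self.rtt.bases + self.pbs.bases
        )
        if self.end_motif is not None:
            seq += self.end_motif.bases
        return rna(seq)

    @property
    def original_pbs_length(self) -> int:
        deleted = sum(
            m.length for m in self.pbs_modifications if m.kind == "deletion"
        )
        return len(self.pbs) + deleted

    @property
    def pbs_origins(self) -> tuple[int, ...]:
        """For each current PBS position, its position in the original PBS."""
        deleted: set[int] = set()
        for m in self.pbs_modifications:
            if m.kind == "deletion":
                deleted.update(range(m.position, m.position + m.length))
        origins = [p for p in range(1, self.original_pbs_length + 1) if p not in deleted]
        assert len(origins) == len(self.pbs)
        return tuple(origins)


@dataclass(frozen=True)
class Pairing:
    spacer_position: int
    pbs_position: int
    is_watson_crick: bool


@dataclass(frozen=True)
class ComplementarityMap:
    """The spacer:PBS pairing register of a design.

    ``pairs`` lists every assigned (spacer position, current PBS position)
    pair; ``n_paired`` counts only Watson-Crick pairs;
    ``covered_spacer_positions`` are the spacer positions with an assigned
    partner; ``register_shifts`` gives, per current PBS position, the
    accumulated shift (+k downstream of a k-nt deletion).
    """

    pairs: tuple[Pairing, ...]
    n_paired: int
    covered_spacer_positions: frozenset[int]
    register_shifts: tuple[int, ...]

    @property
    def max_covered(self) -> int:
        return max(self.covered_spacer_positions, default=0)

    @property
    def fully_paired_pbs(self) -> bool:
        return all(p.is_watson_crick for p in self.pairs)


_RNA_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _wc(a: str, b: str) -> bool:
    return _RNA_PAIR[a] == b


def complementarity_map(
    design: PegDesign, nick_offset: int = DEFAULT_NICK_OFFSET
) -> ComplementarityMap:
    """Assign spacer:PBS pairs by register and evaluate them base-by-base.

    Current PBS position ``p`` with original position ``o`` (from the
    deletion provenance) pairs spacer position ``o + nick_offset`` when that
    position exists on the spacer; Watson-Crick status is read off the
    actual, possibly mismatched, sequences. An appended 5' G is position 21
    and participates like any other position.
    """
    spacer = design.spacer.bases
    spacer_len = len(spacer)
    origins = design.pbs_origins
    scrambled_from = min(
        (m.position for m in design.pbs_modifications if m.kind == "scramble"),
        default=None,
    )
    pairs = []
    shifts = []
    for idx, (base, orig) in enumerate(zip(design.pbs.bases, origins)):
        p = idx + 1
        shifts.append(orig - p)
        spos = orig + nick_offset
        if scrambled_from is not None and p >= scrambled_from:
            # composition was permuted; register identity no longer holds,
            # but the positional assignment (and its WC evaluation) does
            pass
        if 1 <= spos <= spacer_len:
            spacer_base = spacer[spacer_len - spos]
            pairs.append(Pairing(spos, p, _wc(spacer_base, base)))
    covered = frozenset(pr.spacer_position for pr in pairs)
    n_paired = sum(pr.is_watson_crick for pr in pairs)
    return ComplementarityMap(tuple(pairs), n_paired, covered, tuple(shifts))


# --------------------------------------------------------------------------
# Part builders

def build_spacer(
    locus: TargetLocus, u6_mode: bool = True
) -> tuple[NucSeq, bool, list[str]]:
    """RNA spacer from the protospacer; optional U6-driven 5' G append.

    Under ``u6_mode`` a protospacer not starting with G gets a prepended G
    (21-nt spacer) plus a warning: 21-nt spacers showed reduced mismatch
    tolerance and may be less amenable to complementarity-disrupting
    mismatches.
    """
    spacer = to_rna(dna(locus.protospacer))
    warnings: list[str] = []
    appended = False
    if u6_mode and not spacer.bases.startswith("G"):
        spacer = rna("G" + spacer.bases)
        appended = True
        warnings.append(
            "21G: appended 5' G for the U6 promoter; 21-nt spacers may show "
            "reduced mismatch tolerance"
        )
    return spacer, appended, warnings


def build_pbs(
    locus: TargetLocus, length: int, nick_offset: int = DEFAULT_NICK_OFFSET
) -> NucSeq:
    """PBS (RNA, 5'->3'): reverse complement of the primer's 3'-terminal
    ``length`` nucleotides, so PBS position 1 pairs the nick-adjacent base.
    """
    if not 1 <= length <= MAX_PBS_LEN:
        raise DesignError(f"PBS length must be in [1, {MAX_PBS_LEN}]")
    nick = locus.nick_index(nick_offset)
    if nick - length < 0:
        raise DesignError("PBS length exceeds available 5' context")
    primer_3prime = locus.nontarget[nick - length : nick]
    return to_rna(revcomp(dna(primer_3prime)))


def edited_downstream(locus: TargetLocus, edit: EditSpec,
                      nick_offset: int = DEFAULT_NICK_OFFSET) -> str:
    """The non-target strand 3' of the nick with the edit applied (DNA)."""
    nick = locus.nick_index(nick_offset)
    down = locus.nontarget[nick:]
    i = edit.nick_distance - 1
    if edit.edit_type is EditType.INSERTION:
        if i > len(down):
            raise DesignError("insertion point beyond the reference")
        return down[:i] + edit.alt_allele + down[i:]
    ref = edit.ref_allele
    if down[i : i + len(ref)] != ref:
        raise DesignError(
            f"ref_allele {ref!r} does not match the reference "
            f"({down[i:i + len(ref)]!r} at nick_distance {edit.nick_distance})"
        )
    if edit.edit_type is EditType.SUBSTITUTION:
        return down[:i] + edit.alt_allele + down[i + len(ref):]
    return down[:i] + down[i + len(ref):]  # deletion


def default_rtt_length(edit: EditSpec, rha_length: int = 10) -> int:
    """Modest default: cover the edit plus a ``rha_length``-nt homology arm."""
    return edit.nick_distance - 1 + len(edit.alt_allele) + rha_length


def build_rtt(
    locus: TargetLocus,
    edit: EditSpec,
    rtt_length: int | None = None,
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> NucSeq:
    """RTT (RNA, 5'->3'): reverse complement of the first ``rtt_length``
    nucleotides of the *edited* non-target strand 3' of the nick, so that
    reverse-transcribing the RTT from the nick reproduces the edited strand.
    """
    if rtt_length is None:
        rtt_length = default_rtt_length(edit)
    min_len = edit.nick_distance - 1 + len(edit.alt_allele) + 1
    if edit.edit_type is EditType.DELETION:
        min_len = edit.nick_distance  # RHA of >= 1 past the deleted span
    if rtt_length < min_len:
        raise DesignError(
            f"rtt_length {rtt_length} too short to cover the edit plus a "
            f">= 1 nt homology arm (need >= {min_len})"
        )
    edited = edited_downstream(locus, edit, nick_offset)
    if rtt_length > len(edited):
        raise DesignError("rtt_length exceeds the available 3' reference")
    return to_rna(revcomp(dna(edited[:rtt_length])))


def assemble_pegrna(
    spacer: NucSeq,
    scaffold: NucSeq,
    rtt: NucSeq,
    pbs: NucSeq,
    end_motif: NucSeq | None = None,
    **kwargs,
) -> PegDesign:
    """Assemble parts (all RNA) into a PegDesign with empty provenance."""
    return PegDesign(
        spacer=spacer, scaffold=scaffold, rtt=rtt, pbs=pbs, end_motif=end_motif,
        **kwargs,
    )


def design_pegrna(
    locus: TargetLocus,
    edit: EditSpec,
    pbs_length: int = 13,
    rtt_length: int | None = None,
    scaffold: NucSeq = DEFAULT_SCAFFOLD,
    end_motif: NucSeq | None = None,
    u6_mode: bool = True,
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> PegDesign:
    """Build the standard pegRNA for a target/edit pair in one call."""
    spacer, appended, warnings = build_spacer(locus, u6_mode=u6_mode)
    pbs = build_pbs(locus, pbs_length, nick_offset)
    rtt = build_rtt(locus, edit, rtt_length, nick_offset)
    return PegDesign(
        spacer=spacer,
        scaffold=scaffold,
        rtt=rtt,
        pbs=pbs,
        end_motif=end_motif,
        has_appended_5prime_G=appended,
        warnings=tuple(warnings),
    )


def pbs_template(
    locus: TargetLocus, length: int, nick_offset: int = DEFAULT_NICK_OFFSET
) -> NucSeq:
    """The non-target-strand DNA the PBS anneals to (5'->3')."""
    nick = locus.nick_index(nick_offset)
    if nick - length < 0:
        raise DesignError("PBS length exceeds available 5' context")
    return dna(locus.nontarget[nick - length : nick])


def design_report(
    locus: TargetLocus,
    edit: EditSpec,
    pbs_lengths: list[int],
    rtt_length: int | None = None,
    thermo: ThermoConfig = DEFAULT_THERMO,
    nick_offset: int = DEFAULT_NICK_OFFSET,
    u6_mode: bool = True,
) -> pd.DataFrame:
    """One candidate row per PBS length: sequence, Tm, dG(37), pairing.

    Duplicate lengths are deduplicated (first occurrence kept) with a
    warning column entry; the ``tm_dev_37`` column is the |Tm - 37 C|
    ranking hint from the "PBS:non-target strand Tm near 37 C" guideline.
    """
    rows = []
    seen: set[int] = set()
    for length in pbs_lengths:
        dup = length in seen
        seen.add(length)
        if dup:
            continue
        design = design_pegrna(
            locus, edit, pbs_length=length, rtt_length=rtt_length,
            u6_mode=u6_mode, nick_offset=nick_offset,
        )
        cmap = complementarity_map(design, nick_offset)
        report = duplex_tm(design.pbs, pbs_template(locus, length, nick_offset), thermo)
        covered = sorted(cmap.covered_spacer_positions)
        rows.append(
            {
                "pbs_length": length,
                "pbs_sequence": design.pbs.bases,
                "tm_celsius": report.tm_celsius,
                "delta_g_kcal_per_mol": report.delta_g_kcal_per_mol,
                "n_paired": cmap.n_paired,
                "covered_spacer_positions": (
                    f"{covered[0]}-{covered[-1]}" if covered else ""
                ),
                "tm_dev_37": abs(report.tm_celsius - 37.0),
                "warnings": "; ".join(design.warnings),
            }
        )
    columns = [
        "pbs_length", "pbs_sequence", "tm_celsius", "delta_g_kcal_per_mol",
        "n_paired", "covered_spacer_positions", "tm_dev_37", "warnings",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if len(seen) < len(pbs_lengths):
        df.attrs["warnings"] = ["duplicate PBS lengths were deduplicated"]
    return df
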