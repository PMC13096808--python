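"""Nucleic-acid sequence primitives shared by every spellpeg module.

Conventions used throughout the package:

* All genomic coordinates are 0-based, half-open, reported on the forward
  strand of the provided reference.
* DNA and RNA alphabets are strict: a ``U`` in a DNA sequence (or ``T`` in
  RNA) is rejected rather than silently converted, so alphabet bugs surface
  at module boundaries.
* IUPAC ambiguity codes are supported in PAM patterns only, never in
  sequences.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class SpellpegError(ValueError):
    """Base class for all spellpeg input/validation errors."""


class SequenceError(SpellpegError):
    """Invalid sequence content or alphabet misuse."""


class DesignError(SpellpegError):
    """A design operation was asked for something geometrically impossible."""


class Alphabet(enum.Enum):
    DNA = "DNA"
    RNA = "RNA"


_BASES = {Alphabet.DNA: frozenset("ACGT"), Alphabet.RNA: frozenset("ACGU")}

_DNA_COMP = str.maketrans("ACGT", "TGCA")
_RNA_COMP = str.maketrans("ACGU", "UGCA")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CTU")

#: IUPAC ambiguity codes, PAM patterns only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class NucSeq:
    """An immutable nucleic-acid sequence with a declared alphabet.

    Input is case-insensitive and normalized to upper case; any character
    outside the declared alphabet raises :class:`SequenceError`.
    """

    bases: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        normalized = self.bases.upper()
        object.__setattr__(self, "bases", normalized)
        if len(normalized) < 1:
            raise SequenceError("sequence must have length >= 1")
        invalid = set(normalized) - _BASES[self.alphabet]
        if invalid:
            raise SequenceError(
                f"invalid {self.alphabet.value} character(s): {sorted(invalid)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    def __getitem__(self, item) -> str:
        return self.bases[item]


def dna(bases: str) -> NucSeq:
    return NucSeq(bases, Alphabet.DNA)


def rna(bases: str) -> NucSeq:
    return NucSeq(bases, Alphabet.RNA)


def complement(seq: NucSeq) -> NucSeq:
    table = _DNA_COMP if seq.alphabet is Alphabet.DNA else _RNA_COMP
    return NucSeq(seq.bases.translate(table), seq.alphabet)


def revcomp(seq: NucSeq) -> NucSeq:
    """Reverse complement in the same alphabet; an involution."""
    table = _DNA_COMP if seq.alphabet is Alphabet.DNA else _RNA_COMP
    return NucSeq(seq.bases.translate(table)[::-1], seq.alphabet)


def to_rna(seq: NucSeq) -> NucSeq:
    """T -> U transliteration; length-preserving, round-trips with to_dna."""
    if seq.alphabet is Alphabet.RNA:
        return seq
    return NucSeq(seq.bases.replace("T", "U"), Alphabet.RNA)


def to_dna(seq: NucSeq) -> NucSeq:
    if seq.alphabet is Alphabet.DNA:
        return seq
    return NucSeq(seq.bases.replace("U", "T"), Alphabet.DNA)


class SubstitutionClass(enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"


def classify_substitution(ref_base: str, alt_base: str) -> SubstitutionClass:
    """Classify a single-base substitution.

    Transition iff both bases are purines or both pyrimidines (A<->G,
    C<->T/U); transversion otherwise. Identical bases are not a
    substitution and raise.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    for b in (ref_base, alt_base):
        if b not in PURINES | PYRIMIDINES:
            raise SequenceError(f"not a nucleotide base: {b!r}")
    if ref_base == alt_base or {ref_base, alt_base} == {"T", "U"}:
        raise SequenceError(f"{ref_base}->{alt_base} is not a substitution")
    if (ref_base in PURINES) == (alt_base in PURINES):
        return SubstitutionClass.TRANSITION
    return SubstitutionClass.TRANSVERSION


def transition_partner(base: str) -> str:
    """The unique transition partner of a base (RNA or DNA context)."""
    partners = {"A": "G", "G": "A", "C": "T", "T": "C", "U": "C"}
    return partners[base.upper()]


def transversion_partners(base: str, alphabet: Alphabet) -> tuple[str, str]:
    """The two possible transversions of a base, alphabetical order."""
    t = "U" if alphabet is Alphabet.RNA else "T"
    if base.upper() in PURINES:
        return tuple(sorted(("C", t)))  # type: ignore[return-value]
    return ("A", "G")


@dataclass(frozen=True)
class ProtospacerHit:
    """A 20-nt protospacer immediately 5' of a PAM match.

    ``start``/``end`` delimit the protospacer on the forward strand of the
    scanned sequence (0-based, half-open); ``strand`` says which strand the
    protospacer+PAM read 5'->3' on.
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    pam: str


def _pam_regex(pam_pattern: str) -> re.Pattern[str]:
    try:
        parts = [IUPAC[c] for c in pam_pattern.upper()]
    except KeyError as exc:
        raise SequenceError(f"invalid IUPAC code in PAM pattern: {exc}") from exc
    return re.compile("".join(f"[{p}]" if len(p) > 1 else p for p in parts))


def find_protospacers(
    seq: NucSeq, pam_pattern: str = "NGG", spacer_len: int = 20
) -> list[ProtospacerHit]:
    """Scan both strands for ``spacer_len``-nt protospacers 5' of a PAM.

    Overlapping hits are all reported. Coordinates are on the forward
    strand of ``seq``.
    """
    if seq.alphabet is not Alphabet.DNA:
        raise SequenceError("protospacer scan requires a DNA sequence")
    if len(seq) < spacer_len + len(pam_pattern):
        raise SequenceError(
            f"sequence shorter than spacer+PAM ({spacer_len + len(pam_pattern)} nt)"
        )
    pat = _pam_regex(pam_pattern)
    n, k = len(seq), len(pam_pattern)
    hits: list[ProtospacerHit] = []
    fwd = seq.bases
    for i in range(spacer_len, n - k + 1):
        if pat.fullmatch(fwd, i, i + k):
            hits.append(ProtospacerHit(i - spacer_len, i, "+", fwd[i : i + k]))
    rev = revcomp(seq).bases
    for i in range(spacer_len, n - k + 1):
        if pat.fullmatch(rev, i, i + k):
            # protospacer occupies rev[i-spacer_len:i]; map back to forward
            fstart = n - i
            hits.append(
                ProtospacerHit(fstart, fstart + spacer_len, "-", rev[i : i + k])
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# --------------------------------------------------------------------------
# FASTA I/O (Biopython-backed; 60-column wrap on write)

def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.DNA) -> list[tuple[str, NucSeq]]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, NucSeq(str(rec.seq), alphabet)))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, NucSeq]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(str(seq)), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")
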