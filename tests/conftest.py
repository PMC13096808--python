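"""Shared fixtures: programmatic loci, edits, and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from spellpeg import EditSpec, TargetLocus, dna
from spellpeg.pegdesign import PROTOSPACER_LEN

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_locus(rng: np.random.Generator, upstream: int = 30,
               downstream: int = 30) -> TargetLocus:
    """A random locus with an AGG PAM planted after a random protospacer."""
    ref = _random_dna(rng, upstream) + _random_dna(rng, PROTOSPACER_LEN) + \
        "A" + "GG" + _random_dna(rng, downstream)
    return TargetLocus(dna(ref), upstream, "+")


def simple_substitution(locus: TargetLocus, nick_distance: int = 1) -> EditSpec:
    """A 1-nt transition at the given distance 3' of the nick."""
    nick = locus.nick_index()
    ref_base = locus.nontarget[nick + nick_distance - 1]
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    return EditSpec.substitution(nick_distance, ref_base, alt)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def locus(rng) -> TargetLocus:
    return make_locus(rng)


@pytest.fixture
def edit(locus) -> EditSpec:
    return simple_substitution(locus)


@pytest.fixture
def example_locus() -> TargetLocus:
    """The worked protospacer example: PAM-proximal->distal bases
    C,C,T,A,T,C,G,C,A,A,G,G,T,T,C,C,A,C,T,G with an AGG PAM."""
    proto_by_position = "CCTATCGCAAGGTTCCACTG"  # position 1 .. 20
    proto_fwd = proto_by_position[::-1]
    rng = np.random.default_rng(0)
    ref = _random_dna(rng, 30) + proto_fwd + "AGG" + _random_dna(rng, 30)
    return TargetLocus(dna(ref), 30, "+")


# --------------------------------------------------------------------------
# independent oracles (string-level, no spellpeg internals)

def oracle_spacer(locus: TargetLocus, u6_mode: bool = True,
                  mismatches: dict[int, str] | None = None) -> str:
    """Spacer RNA from the genome, with optional {position: alt} mismatches."""
    s = locus.protospacer.replace("T", "U")
    if u6_mode and not s.startswith("G"):
        s = "G" + s
    for pos, alt in (mismatches or {}).items():
        i = len(s) - pos
        s = s[:i] + alt + s[i + 1:]
    return s


def oracle_complementarity(
    locus: TargetLocus,
    pbs_length: int,
    deletions: list[tuple[int, int]] = (),
    spacer_mismatches: dict[int, str] | None = None,
    pbs_mismatches: dict[int, str] | None = None,
    u6_mode: bool = True,
    nick_offset: int = 3,
) -> tuple[int, set[int]]:
    """Brute-force (n_paired, covered positions) from genomic strings alone.

    The PBS base at original position o is read directly off the non-target
    strand (complement of the base o nucleotides 5' of the nick); o pairs
    spacer position o + nick_offset whenever that spacer position exists.
    """
    spacer = oracle_spacer(locus, u6_mode, spacer_mismatches)
    nick = locus.protospacer_start + PROTOSPACER_LEN - nick_offset
    deleted: set[int] = set()
    for start, length in deletions:
        deleted.update(range(start, start + length))
    n_paired = 0
    covered: set[int] = set()
    for o in range(1, pbs_length + 1):
        if o in deleted:
            continue
        spos = o + nick_offset
        if spos > len(spacer):
            continue
        covered.add(spos)
        pbs_base = _COMP[locus.nontarget[nick - o]].replace("T", "U")
        if pbs_mismatches and o in pbs_mismatches:
            pbs_base = pbs_mismatches[o]
        if _RNA_PAIR[spacer[len(spacer) - spos]] == pbs_base:
            n_paired += 1
    return n_paired, covered
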