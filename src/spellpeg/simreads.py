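"""Deterministic synthetic amplicon-read simulator with a known truth table.

Emulates the read classes an amplicon quantifier must distinguish: unedited
reads, intended-edit reads, reads with indels around the nick site(s), and
(optionally) intended-edit reads that also carry an indel. Class counts are
made exact by largest-remainder rounding of the configured fractions, and a
uniform substitution sequencing error is sprinkled on top. With the same
seed the simulator is bit-identical.

By default no sequencing error is placed inside the edit +/- flank window
of intended-edit reads, so with error rate 0 (and any rate, for the edit
motif) the quantifier's recovery is exact — this separates classifier
correctness from error-robustness testing. A flag lifts the protection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqcore import Alphabet, DesignError, NucSeq, SequenceError
from .pegdesign import EditSpec, EditType

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class IndelClass:
    """One indel read class: an insertion/deletion near the nick.

    ``offset`` is counted in nucleotides from the nick's between-base
    coordinate: a deletion removes reference bases starting ``offset``
    bases 3' of the nick (may be negative); an insertion is placed at the
    between-base coordinate nick+offset. ``on_edited`` stacks the indel on
    top of the intended edit.
    """

    offset: int
    kind: str  # 'ins' | 'del'
    length: int
    fraction: float
    on_edited: bool = False

    @property
    def label(self) -> str:
        tag = f"{self.kind}{self.length}@{self.offset:+d}"
        return f"intended_edit+{tag}" if self.on_edited else tag


@dataclass(frozen=True)
class ReadSimConfig:
    reference_amplicon: NucSeq
    nick_site: int  # 0-based between-base coordinate on the reference
    intended_edit: EditSpec  # nick-relative, as everywhere in the package
    edit_fraction: float
    indel_spectrum: tuple[IndelClass, ...] = ()
    sequencing_error_rate: float = 0.0
    n_reads: int = 1000
    read_length: int | None = None  # None: full amplicon
    seed: int | None = None
    edit_window_flank: int = 5
    protect_edit_flanks: bool = True

    def __post_init__(self) -> None:
        if self.reference_amplicon.alphabet is not Alphabet.DNA:
            raise SequenceError("reference amplicon must be DNA")
        if self.seed is None:
            raise DesignError("a seed is mandatory for reproducible simulation")
        if not 0 <= self.edit_fraction <= 1:
            raise DesignError("edit_fraction must be in [0, 1]")
        if not 0 <= self.sequencing_error_rate < 1:
            raise DesignError("sequencing_error_rate must be in [0, 1)")
        total = self.edit_fraction + sum(c.fraction for c in self.indel_spectrum)
        if total > 1 + 1e-9:
            raise DesignError(f"class fractions sum to {total} > 1")
        if not 0 < self.nick_site < len(self.reference_amplicon):
            raise DesignError("nick_site must lie inside the reference")


@dataclass(frozen=True)
class TruthTable:
    """Per-read labels and exact per-class counts for a simulated run."""

    labels: tuple[str, ...]
    counts: dict[str, int]
    class_sequences: dict[str, str]

    @property
    def n_reads(self) -> int:
        return len(self.labels)

    def fraction(self, label: str) -> float:
        return self.counts.get(label, 0) / self.n_reads

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tlabel\n")
            for i, label in enumerate(self.labels):
                fh.write(f"r{i:06d}\t{label}\n")


def _apply_edit(ref: str, nick: int, edit: EditSpec) -> str:
    i = nick + edit.nick_distance - 1
    if edit.edit_type is EditType.INSERTION:
        return ref[:i] + edit.alt_allele + ref[i:]
    if ref[i : i + len(edit.ref_allele)] != edit.ref_allele:
        raise DesignError("intended_edit ref_allele does not match the amplicon")
    if edit.edit_type is EditType.SUBSTITUTION:
        return ref[:i] + edit.alt_allele + ref[i + len(edit.ref_allele):]
    return ref[:i] + ref[i + len(edit.ref_allele):]


def _apply_indel(seq: str, pos: int, cls: IndelClass, rng: np.random.Generator,
                 avoid: str) -> str:
    if cls.kind == "del":
        if pos < 0 or pos + cls.length > len(seq):
            raise DesignError(f"indel class {cls.label} falls off the amplicon")
        return seq[:pos] + seq[pos + cls.length:]
    if cls.kind == "ins":
        # fixed per-class insert, chosen so its first base differs from the
        # reference continuation (cannot silently recreate the reference)
        while True:
            ins = "".join(rng.choice(list("ACGT"), size=cls.length))
            shifts_ref = pos >= len(seq) or ins[0] != seq[pos]
            if shifts_ref and ins != avoid:
                break
        return seq[:pos] + ins + seq[pos:]
    raise DesignError(f"unknown indel kind {cls.kind!r}")


def _largest_remainder(fractions: list[float], n: int) -> list[int]:
    exact = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in exact]
    short = round(n * sum(fractions)) - sum(counts)
    order = np.argsort([c - e for c, e in zip(counts, exact)])
    for i in range(short):
        counts[order[i]] += 1
    return counts


def simulate_amplicon_reads(
    cfg: ReadSimConfig,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Generate reads and their truth table; deterministic given cfg.seed.

    Returns ``(reads, truth)`` where reads is a list of (read_id, sequence)
    in FASTQ order and ``truth.labels[i]`` labels ``reads[i]``.
    """
    ref = cfg.reference_amplicon.bases
    nick = cfg.nick_site
    rng = np.random.default_rng(cfg.seed)

    edited = _apply_edit(ref, nick, cfg.intended_edit)
    # protected motif span (in read coordinates; identical for ref/edited
    # upstream of the edit): edit start - flank .. edit end + flank
    e0 = nick + cfg.intended_edit.nick_distance - 1
    alt_len = len(cfg.intended_edit.alt_allele)
    protect = (max(0, e0 - cfg.edit_window_flank), e0 + alt_len + cfg.edit_window_flank)

    class_seqs: dict[str, str] = {"unedited": ref, "intended_edit": edited}
    labels = ["intended_edit"] + [c.label for c in cfg.indel_spectrum]
    for cls in cfg.indel_spectrum:
        base = edited if cls.on_edited else ref
        class_seqs[cls.label] = _apply_indel(
            base, nick + cls.offset, cls, rng, avoid=cfg.intended_edit.alt_allele
        )

    read_len = cfg.read_length or len(ref)
    min_len = protect[1] + 10
    if read_len < min_len:
        raise DesignError(
            f"read_length {read_len} shorter than edit window + 10 ({min_len})"
        )

    fractions = [cfg.edit_fraction] + [c.fraction for c in cfg.indel_spectrum]
    counts = _largest_remainder(fractions, cfg.n_reads)
    n_unedited = cfg.n_reads - sum(counts)
    all_labels = ["unedited"] * n_unedited
    for label, count in zip(labels, counts):
        all_labels.extend([label] * count)
    order = rng.permutation(cfg.n_reads)
    shuffled = [all_labels[i] for i in order]

    protected = {"intended_edit"} | {
        c.label for c in cfg.indel_spectrum if c.on_edited
    }
    reads: list[tuple[str, str]] = []
    err = cfg.sequencing_error_rate
    truncated = {lab: seq[:read_len] for lab, seq in class_seqs.items()}
    arrs = {
        lab: np.frombuffer(seq.encode(), dtype=np.uint8)
        for lab, seq in truncated.items()
    }
    n_errors = (
        rng.binomial(
            [len(truncated[lab]) for lab in shuffled], err
        )
        if err > 0
        else np.zeros(cfg.n_reads, dtype=int)
    )
    for i, label in enumerate(shuffled):
        seq = truncated[label]
        k = int(n_errors[i])
        if k:
            arr = arrs[label].copy()
            positions = rng.integers(0, len(arr), size=k)
            if cfg.protect_edit_flanks and label in protected:
                positions = positions[
                    (positions < protect[0]) | (positions >= protect[1])
                ]
            for pos in positions:
                choices = _BASES[_BASES != arr[pos]]
                arr[pos] = rng.choice(choices)
            seq = arr.tobytes().decode()
        reads.append((f"r{i:06d}", seq))

    counts_by_label: dict[str, int] = {"unedited": n_unedited}
    for label, count in zip(labels, counts):
        counts_by_label[label] = count
    truth = TruthTable(tuple(shuffled), counts_by_label, class_seqs)
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path,
                quality_char: str = "F") -> None:
    """Plain 4-line FASTQ, constant quality (default Q37, Phred+33)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
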