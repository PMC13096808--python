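"""pegRNA variant generation: the complementarity-disruption strategies.

Variant classes
---------------
* spacer mismatches — substitutions in the guide segment, most useful in the
  PAM-distal (position > 10) PBS-complementary region; PAM-proximal
  mismatches frequently cost nicking activity and positions outside the
  PBS-complementary region cannot weaken the spacer:PBS duplex at all, so
  both cases attract advisory warnings.
* PBS mismatches — complement-breaking substitutions in the PBS; with short
  PBSs (<= 13 nt) these mostly reduced editing, which is warned about.
* PBS deletions — 1-4 nt consecutive deletions at starts 6-15 of a long
  PBS; each variant records the intact 5' segment it is equivalent to, and
  deletions that collapse to the same sequence are flagged as duplicates.
* SPELL — a 17-20 nt PBS with a single-nucleotide deletion (default:
  position 13 of a 20-nt PBS, leaving a 12-nt intact 5' segment).
* PBS-end scrambles — seeded permutations of the PBS 3' segment with zero
  Watson-Crick pairs left in the spacer register, for separating annealing
  from non-annealing contributions of the PBS end.
* combinations — deletions plus mismatches, positions quoted in the
  original part's coordinates.

Warnings are advisory, never blocking: the underlying screens show
exceptions in both directions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .seqcore import (
    Alphabet,
    DesignError,
    NucSeq,
    SubstitutionClass,
    classify_substitution,
    rna,
    transition_partner,
    transversion_partners,
)
from .pegdesign import (
    DEFAULT_NICK_OFFSET,
    ComplementarityMap,
    EditSpec,
    PbsModification,
    PegDesign,
    SpacerMismatch,
    TargetLocus,
    build_pbs,
    complementarity_map,
    design_pegrna,
)

_RNA_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}

PAM_PROXIMAL_LIMIT = 10
SPELL_PBS_RANGE = (17, 20)
SPELL_DEFAULT_PBS = 20
SPELL_DEFAULT_DELETION = 13


class VariantKind(enum.Enum):
    SPACER_MISMATCH = "spacer_mismatch"
    PBS_MISMATCH = "pbs_mismatch"
    PBS_DELETION = "pbs_deletion"
    PBS_SCRAMBLE = "pbs_scramble"
    COMBO = "combo"
    SPELL = "spell"


@dataclass(frozen=True)
class VariantSpec:
    kind: VariantKind
    positions: tuple[int, ...] = ()
    substitution_class: SubstitutionClass | None = None
    alt_bases: tuple[str, ...] = ()  # explicit override of the tie-break rule
    deletion_length: int | None = None
    seed: int | None = None  # scramble only


@dataclass(frozen=True)
class VariantEntry:
    spec: VariantSpec
    design: PegDesign
    warnings: tuple[str, ...]
    n_paired_delta: int
    duplicate_of: str | None = None  # variant label of an identical sequence
    label: str = ""


@dataclass(frozen=True)
class VariantSet:
    base: PegDesign
    entries: tuple[VariantEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# --------------------------------------------------------------------------
# low-level edits (original-coordinate semantics throughout)

def _spacer_index(design: PegDesign, position: int) -> int:
    n = len(design.spacer)
    if not 1 <= position <= n:
        raise DesignError(f"spacer position out of range: {position}")
    return n - position


def _opposing_pbs_base(design: PegDesign, spacer_position: int,
                       nick_offset: int) -> str | None:
    """The PBS base paired with a spacer position, if covered."""
    cmap = complementarity_map(design, nick_offset)
    for pr in cmap.pairs:
        if pr.spacer_position == spacer_position:
            return design.pbs.bases[pr.pbs_position - 1]
    return None


def _pick_substitution(
    original: str,
    sub_class: SubstitutionClass | None,
    opposing: str | None,
    explicit: str | None,
) -> tuple[str, SubstitutionClass]:
    """Realize a substitution class as a concrete base.

    Transitions are unique. For transversions (or an unspecified class) the
    tie-break is: of the two candidates, prefer one that is also
    non-complementary to the opposing spacer/PBS base; if both (or neither)
    qualify, take the alphabetically first.
    """
    if explicit is not None:
        alt = explicit.upper()
        return alt, classify_substitution(original, alt)
    if sub_class is SubstitutionClass.TRANSITION:
        alt = transition_partner(original)
        if alt == "T":
            alt = "U"
        return alt, SubstitutionClass.TRANSITION
    candidates = list(transversion_partners(original, Alphabet.RNA))
    if opposing is not None:
        noncomp = [c for c in candidates if _RNA_PAIR[c] != opposing]
        if noncomp:
            candidates = noncomp
    return sorted(candidates)[0], SubstitutionClass.TRANSVERSION


def apply_spacer_mismatch(
    design: PegDesign,
    position: int,
    sub_class: SubstitutionClass | None = None,
    alt_base: str | None = None,
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> PegDesign:
    idx = _spacer_index(design, position)
    original = design.spacer.bases[idx]
    if any(m.position == position for m in design.spacer_mismatches):
        raise DesignError(f"spacer position {position} already mismatched")
    opposing = _opposing_pbs_base(design, position, nick_offset)
    alt, realized = _pick_substitution(original, sub_class, opposing, alt_base)
    if alt == original:
        raise DesignError(f"substitution at spacer {position} is a no-op")
    bases = design.spacer.bases
    new_spacer = rna(bases[:idx] + alt + bases[idx + 1 :])
    return replace(
        design,
        spacer=new_spacer,
        spacer_mismatches=design.spacer_mismatches
        + (SpacerMismatch(position, alt, realized),),
    )


def _current_pbs_index(design: PegDesign, original_position: int) -> int:
    origins = design.pbs_origins
    if original_position in origins:
        return origins.index(original_position)
    if 1 <= original_position <= design.original_pbs_length:
        raise DesignError(
            f"PBS position {original_position} was deleted by a prior modification"
        )
    raise DesignError(f"PBS position out of range: {original_position}")


def apply_pbs_mismatch(
    design: PegDesign,
    position: int,
    alt_base: str | None = None,
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> PegDesign:
    """Complement-breaking substitution at an (original) PBS position."""
    idx = _current_pbs_index(design, position)
    original = design.pbs.bases[idx]
    spacer_position = position + nick_offset
    opposing = None
    if 1 <= spacer_position <= len(design.spacer):
        opposing = design.spacer.bases[len(design.spacer) - spacer_position]
    alt, _ = _pick_substitution(original, None, opposing, alt_base)
    if alt == original:
        raise DesignError(f"substitution at PBS {position} is a no-op")
    bases = design.pbs.bases
    new_pbs = rna(bases[:idx] + alt + bases[idx + 1 :])
    return replace(
        design,
        pbs=new_pbs,
        pbs_modifications=design.pbs_modifications
        + (PbsModification(position, "mismatch", 1, alt),),
    )


def apply_pbs_deletion(
    design: PegDesign, start: int, length: int = 1
) -> PegDesign:
    """Delete ``length`` consecutive PBS nucleotides at original position
    ``start``; downstream positions keep their original register."""
    if length < 1:
        raise DesignError("deletion length must be >= 1")
    span = range(start, start + length)
    origins = design.pbs_origins
    for p in span:
        if p not in origins:
            raise DesignError(
                f"PBS position {p} unavailable for deletion (out of range or "
                "already modified)"
            )
    keep = [i for i, o in enumerate(origins) if o not in span]
    if len(keep) < 3:
        raise DesignError("deletion would leave a PBS shorter than 3 nt")
    new_pbs = rna("".join(design.pbs.bases[i] for i in keep))
    return replace(
        design,
        pbs=new_pbs,
        pbs_modifications=design.pbs_modifications
        + (PbsModification(start, "deletion", length),),
    )


# --------------------------------------------------------------------------
# variant-set generators

def _entry(
    base: PegDesign,
    cmap_base: ComplementarityMap,
    spec: VariantSpec,
    design: PegDesign,
    warnings: list[str],
    label: str,
    nick_offset: int,
) -> VariantEntry:
    cmap = complementarity_map(design, nick_offset)
    return VariantEntry(
        spec=spec,
        design=design,
        warnings=tuple(warnings),
        n_paired_delta=cmap.n_paired - cmap_base.n_paired,
        label=label,
    )


def spacer_mismatch_variants(
    base: PegDesign,
    positions: list[int],
    classes: list[SubstitutionClass | str] | None = None,
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> VariantSet:
    """One variant per (position, class); ``classes`` entries may also be
    explicit alternative bases. Placement warnings follow the screen's
    findings (PAM-proximal <= 10; outside the PBS-complementary region).
    """
    if classes is None:
        classes = [SubstitutionClass.TRANSVERSION] * len(positions)
    if len(classes) != len(positions):
        raise DesignError("positions and classes must have equal length")
    cmap_base = complementarity_map(base, nick_offset)
    entries = []
    for position, cls in zip(positions, classes):
        alt = None
        sub_class = None
        if isinstance(cls, SubstitutionClass):
            sub_class = cls
        else:
            alt = str(cls)
        design = apply_spacer_mismatch(base, position, sub_class, alt, nick_offset)
        warnings = []
        if position <= PAM_PROXIMAL_LIMIT:
            warnings.append(
                f"PAM-proximal mismatch (position {position} <= "
                f"{PAM_PROXIMAL_LIMIT}): PE efficiency frequently decreased"
            )
        if position not in cmap_base.covered_spacer_positions:
            warnings.append(
                f"position {position} is outside the PBS-complementary "
                "region: no benefit expected"
            )
        realized = design.spacer_mismatches[-1]
        spec = VariantSpec(
            VariantKind.SPACER_MISMATCH,
            (position,),
            substitution_class=realized.substitution_class,
            alt_bases=(realized.alt_base,),
        )
        entries.append(
            _entry(base, cmap_base, spec, design, warnings,
                   f"spacer_mm_{position}{realized.alt_base}", nick_offset)
        )
    return VariantSet(base, tuple(entries))


def pbs_mismatch_variants(
    base: PegDesign,
    position_sets: list[int | list[int]],
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> VariantSet:
    """Complement-breaking PBS substitutions.

    Each element of ``position_sets`` yields one variant: an int gives a
    single mismatch, a list gives simultaneous mismatches (the long-PBS
    screens applied several at once).
    """
    cmap_base = complementarity_map(base, nick_offset)
    short_pbs = len(base.pbs) <= 13
    entries = []
    for group in position_sets:
        positions = [group] if isinstance(group, int) else list(group)
        design = base
        for p in positions:
            design = apply_pbs_mismatch(design, p, nick_offset=nick_offset)
        warnings = []
        if short_pbs:
            warnings.append(
                "short-PBS mismatches (<= 13 nt) mostly reduced efficiency"
            )
        spec = VariantSpec(VariantKind.PBS_MISMATCH, tuple(positions))
        label = "pbs_mm_" + "_".join(map(str, positions))
        entries.append(
            _entry(base, cmap_base, spec, design, warnings, label, nick_offset)
        )
    return VariantSet(base, tuple(entries))


def pbs_deletion_variants(
    base: PegDesign,
    start_positions: list[int] | None = None,
    lengths: list[int] | None = None,
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> VariantSet:
    """All (start, length) consecutive PBS deletions; defaults reproduce the
    screened grid, starts 6-15 x lengths 1-4. Variants whose resulting PBS
    collapses to a sequence seen earlier in the grid are flagged duplicates.
    """
    start_positions = list(start_positions or range(6, 16))
    lengths = list(lengths or range(1, 5))
    needed = max(start_positions) + max(lengths) - 1
    if len(base.pbs) < needed:
        raise DesignError(
            f"base PBS ({len(base.pbs)} nt) shorter than max(start)+max(len)-1"
            f" = {needed}"
        )
    cmap_base = complementarity_map(base, nick_offset)
    entries = []
    seen: dict[str, str] = {}
    for start in start_positions:
        for length in lengths:
            design = apply_pbs_deletion(base, start, length)
            warnings = []
            if not 1 <= length <= 4:
                warnings.append(
                    f"deletion length {length} outside the screened 1-4 nt range"
                )
            label = f"pbs_del_{start}x{length}"
            dup = seen.get(design.pbs.bases)
            if dup is None:
                seen[design.pbs.bases] = label
            spec = VariantSpec(
                VariantKind.PBS_DELETION, (start,), deletion_length=length
            )
            entry = _entry(base, cmap_base, spec, design, warnings, label,
                           nick_offset)
            entries.append(replace(entry, duplicate_of=dup))
    return VariantSet(base, tuple(entries))


def intact_upstream_segment(design: PegDesign) -> str:
    """The unmodified PBS 5' segment preceding the first deletion (RNA)."""
    first_del = min(
        (m.position for m in design.pbs_modifications if m.kind == "deletion"),
        default=None,
    )
    if first_del is None:
        return design.pbs.bases
    return design.pbs.bases[: first_del - 1]


def make_spell(
    locus: TargetLocus,
    edit: EditSpec,
    pbs_length: int = SPELL_DEFAULT_PBS,
    deletion_position: int = SPELL_DEFAULT_DELETION,
    rtt_length: int | None = None,
    nick_offset: int = DEFAULT_NICK_OFFSET,
    **design_kwargs,
) -> PegDesign:
    """A SPELL pegRNA: 17-20 nt PBS with one single-nucleotide deletion.

    Defaults (PBS20, deletion at position 13) leave a 12-nt intact 5'
    segment identical to the plain 12-nt PBS, plus a register-shifted 3'
    segment. Lengths outside 17-20 are allowed with a warning.
    """
    if deletion_position >= pbs_length:
        raise DesignError(
            f"deletion position {deletion_position} must be < pbs_length "
            f"{pbs_length}"
        )
    warnings: list[str] = []
    lo, hi = SPELL_PBS_RANGE
    if not lo <= pbs_length <= hi:
        warnings.append(
            f"SPELL PBS length {pbs_length} outside the recommended "
            f"{lo}-{hi} nt range"
        )
    design = design_pegrna(
        locus, edit, pbs_length=pbs_length, rtt_length=rtt_length,
        nick_offset=nick_offset, **design_kwargs,
    )
    design = apply_pbs_deletion(design, deletion_position, 1)
    return replace(
        design,
        provenance="spell",
        warnings=design.warnings + tuple(warnings),
    )


def scramble_pbs_end(
    base: PegDesign,
    from_position: int,
    seed: int,
    nick_offset: int = DEFAULT_NICK_OFFSET,
    max_retries: int = 200,
) -> PegDesign:
    """Replace PBS positions >= ``from_position`` (current coordinates) by a
    seeded random permutation of themselves that differs from the original
    and leaves zero Watson-Crick pairs in the spacer register; composition
    is preserved by construction.
    """
    if not 1 <= from_position <= len(base.pbs):
        raise DesignError(f"from_position out of range: {from_position}")
    segment = base.pbs.bases[from_position - 1 :]
    if len(set(segment)) < 2:
        raise DesignError("segment too homopolymeric to permute distinctly")
    origins = base.pbs_origins
    spacer = base.spacer.bases
    n_spacer = len(spacer)
    rng = np.random.default_rng(seed)
    letters = np.array(list(segment))
    for _ in range(max_retries):
        perm = "".join(rng.permutation(letters))
        if perm == segment:
            continue
        clash = False
        for offset, b in enumerate(perm):
            spos = origins[from_position - 1 + offset] + nick_offset
            if 1 <= spos <= n_spacer and _RNA_PAIR[spacer[n_spacer - spos]] == b:
                clash = True
                break
        if not clash:
            new_pbs = rna(base.pbs.bases[: from_position - 1] + perm)
            return replace(
                base,
                pbs=new_pbs,
                pbs_modifications=base.pbs_modifications
                + (PbsModification(from_position, "scramble", len(segment)),),
                provenance=base.provenance + "+scramble",
            )
    raise DesignError(
        f"no acceptable permutation found in {max_retries} retries"
    )


def combine(
    base: PegDesign,
    specs: list[VariantSpec],
    nick_offset: int = DEFAULT_NICK_OFFSET,
) -> PegDesign:
    """Apply several variant specs to one design, deletions first, with all
    positions interpreted in the ORIGINAL part's coordinates.

    Mutually incompatible specs (two edits touching one position) raise an
    error listing the collision.
    """
    if not specs:
        return base
    touched: dict[tuple[str, int], VariantSpec] = {}
    for spec in specs:
        part = "spacer" if spec.kind is VariantKind.SPACER_MISMATCH else "pbs"
        length = spec.deletion_length or 1
        for p in spec.positions:
            span = range(p, p + length) if spec.kind is VariantKind.PBS_DELETION \
                else (p,)
            for q in span:
                key = (part, q)
                if key in touched:
                    raise DesignError(
                        f"conflicting specs at {part} position {q}: "
                        f"{touched[key].kind.value} vs {spec.kind.value}"
                    )
                touched[key] = spec
    order = {
        VariantKind.PBS_DELETION: 0,
        VariantKind.SPELL: 0,
        VariantKind.PBS_MISMATCH: 1,
        VariantKind.SPACER_MISMATCH: 2,
        VariantKind.PBS_SCRAMBLE: 3,
    }
    design = base
    for spec in sorted(specs, key=lambda s: (order.get(s.kind, 9),
                                             s.positions)):
        if spec.kind is VariantKind.PBS_DELETION:
            for p in spec.positions:
                design = apply_pbs_deletion(design, p, spec.deletion_length or 1)
        elif spec.kind is VariantKind.PBS_MISMATCH:
            for i, p in enumerate(spec.positions):
                alt = spec.alt_bases[i] if spec.alt_bases else None
                design = apply_pbs_mismatch(design, p, alt, nick_offset)
        elif spec.kind is VariantKind.SPACER_MISMATCH:
            for i, p in enumerate(spec.positions):
                alt = spec.alt_bases[i] if spec.alt_bases else None
                design = apply_spacer_mismatch(
                    design, p, spec.substitution_class, alt, nick_offset
                )
        elif spec.kind is VariantKind.PBS_SCRAMBLE:
            if spec.seed is None:
                raise DesignError("scramble spec requires a seed")
            design = scramble_pbs_end(
                design, spec.positions[0], spec.seed, nick_offset
            )
        else:
            raise DesignError(f"cannot combine spec of kind {spec.kind}")
    return replace(design, provenance="combo")


# --------------------------------------------------------------------------
# export

def variant_set_to_frame(vs: VariantSet,
                         nick_offset: int = DEFAULT_NICK_OFFSET) -> pd.DataFrame:
    rows = []
    for e in vs.entries:
        cmap = complementarity_map(e.design, nick_offset)
        rows.append(
            {
                "label": e.label,
                "kind": e.spec.kind.value,
                "positions": ",".join(map(str, e.spec.positions)),
                "spacer": e.design.spacer.bases,
                "pbs": e.design.pbs.bases,
                "rtt": e.design.rtt.bases,
                "full_sequence": e.design.full_sequence.bases,
                "n_paired": cmap.n_paired,
                "n_paired_delta": e.n_paired_delta,
                "duplicate_of": e.duplicate_of or "",
                "warnings": "; ".join(e.warnings),
            }
        )
    return pd.DataFrame(rows)


def variant_set_to_fasta(vs: VariantSet) -> list[tuple[str, NucSeq]]:
    return [(e.label, e.design.full_sequence) for e in vs.entries]
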