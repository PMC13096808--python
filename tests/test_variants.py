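"""Variant generation: mismatches, deletions, SPELL, scrambles, combos."""

import numpy as np
import pytest

from spellpeg import (
    DesignError,
    SubstitutionClass,
    complementarity_map,
    design_pegrna,
)
from spellpeg.pegdesign import build_pbs
from spellpeg.variants import (
    VariantKind,
    VariantSpec,
    combine,
    intact_upstream_segment,
    make_spell,
    pbs_deletion_variants,
    pbs_mismatch_variants,
    scramble_pbs_end,
    spacer_mismatch_variants,
    variant_set_to_frame,
)

from conftest import make_locus, oracle_complementarity, simple_substitution


@pytest.fixture
def base20(locus, edit):
    return design_pegrna(locus, edit, pbs_length=20, u6_mode=False)


@pytest.fixture
def base17(locus, edit):
    return design_pegrna(locus, edit, pbs_length=17, u6_mode=False)


# --------------------------------------------------------------------------
# spacer mismatches

def test_single_distal_mismatch_drops_one_pair(base17):
    vs = spacer_mismatch_variants(base17, [13])
    (entry,) = vs.entries
    assert entry.n_paired_delta == -1
    assert not entry.warnings
    assert complementarity_map(entry.design).n_paired == 16


def test_pam_proximal_mismatch_warns(base17):
    vs = spacer_mismatch_variants(base17, [8])
    assert any("PAM-proximal" in w for w in vs.entries[0].warnings)


def test_mismatch_outside_complementary_region_warns(locus, edit):
    base10 = design_pegrna(locus, edit, pbs_length=10, u6_mode=False)
    vs = spacer_mismatch_variants(base10, [15])  # covered region ends at 13
    (entry,) = vs.entries
    assert entry.n_paired_delta == 0
    assert any("outside" in w for w in entry.warnings)


def test_transition_is_unique_and_explicit_base_respected(base17):
    pos = 12
    original = base17.spacer.bases[len(base17.spacer) - pos]
    vs = spacer_mismatch_variants(base17, [pos], [SubstitutionClass.TRANSITION])
    realized = vs.entries[0].design.spacer_mismatches[0]
    assert realized.substitution_class is SubstitutionClass.TRANSITION
    alt = "A" if original != "A" else "G"
    vs2 = spacer_mismatch_variants(base17, [pos], [alt])
    assert vs2.entries[0].design.spacer_mismatches[0].alt_base == alt


def test_every_mismatch_breaks_exactly_covered_pairs(rng):
    """Exhaustive: a single spacer mismatch drops n_paired by 1 at covered
    positions and by 0 elsewhere, over positions 1-20 x PBS lengths 4-20."""
    locus = make_locus(rng)
    edit = simple_substitution(locus)
    for length in range(4, 21):
        base = design_pegrna(locus, edit, pbs_length=length, u6_mode=False)
        covered = complementarity_map(base).covered_spacer_positions
        n0 = complementarity_map(base).n_paired
        for pos in range(1, 21):
            variant = spacer_mismatch_variants(base, [pos]).entries[0]
            expected = -1 if pos in covered else 0
            assert variant.n_paired_delta == expected, (length, pos)
            assert n0 + expected == complementarity_map(variant.design).n_paired


# --------------------------------------------------------------------------
# PBS mismatches

def test_pbs20_simultaneous_mismatches_are_one_variant(base20):
    vs = pbs_mismatch_variants(base20, [[14, 16, 18]])
    (entry,) = vs.entries
    assert len([m for m in entry.design.pbs_modifications
                if m.kind == "mismatch"]) == 3
    assert not entry.warnings  # long PBS: no short-PBS warning


def test_short_pbs_mismatch_warns(locus, edit):
    base10 = design_pegrna(locus, edit, pbs_length=10, u6_mode=False)
    vs = pbs_mismatch_variants(base10, [6])
    assert any("short-PBS" in w for w in vs.entries[0].warnings)
    assert vs.entries[0].n_paired_delta == -1


def test_pbs_mismatch_out_of_bounds(base20):
    with pytest.raises(DesignError):
        pbs_mismatch_variants(base20, [21])


# --------------------------------------------------------------------------
# PBS deletions

def test_deletion_grid_yields_40_variants(base20):
    vs = pbs_deletion_variants(base20)
    assert len(vs) == 40


def test_deletion_at_13_leaves_intact_12(base20, locus):
    vs = pbs_deletion_variants(base20, [13], [1])
    design = vs.entries[0].design
    assert intact_upstream_segment(design) == build_pbs(locus, 12).bases
    assert len(design.pbs) == 19


def test_homopolymer_deletions_flag_duplicates(rng, monkeypatch):
    # plant a homopolymer run inside the PBS-template region
    while True:
        locus = make_locus(rng)
        nick = locus.nick_index()
        ref = locus.reference.bases
        ref = ref[: nick - 10] + "AAAA" + ref[nick - 6 :]
        try:
            from spellpeg import TargetLocus, dna
            locus2 = TargetLocus(dna(ref), locus.protospacer_start, "+")
            break
        except DesignError:
            continue
    edit = simple_substitution(locus2)
    base = design_pegrna(locus2, edit, pbs_length=20, u6_mode=False)
    vs = pbs_deletion_variants(base, [7, 8, 9], [1])
    dupes = [e for e in vs.entries if e.duplicate_of]
    assert dupes, "adjacent deletions in a homopolymer must collapse"


def test_deletion_cannot_leave_pbs_below_3nt(locus, edit):
    base5 = design_pegrna(locus, edit, pbs_length=5, u6_mode=False)
    with pytest.raises(DesignError):
        pbs_deletion_variants(base5, [2], [3])


# --------------------------------------------------------------------------
# SPELL

def test_spell_defaults(locus, edit):
    design = make_spell(locus, edit, u6_mode=False)
    assert len(design.pbs) == 19
    assert design.provenance == "spell"
    assert intact_upstream_segment(design) == build_pbs(locus, 12).bases


def test_spell_pbs17(locus, edit):
    design = make_spell(locus, edit, pbs_length=17, u6_mode=False)
    assert len(design.pbs) == 16
    assert intact_upstream_segment(design) == build_pbs(locus, 12).bases


def test_spell_intact_segment_property(rng):
    """make_spell(L, del@d)'s intact 5' segment equals build_pbs(d-1)."""
    locus = make_locus(rng)
    edit = simple_substitution(locus)
    for length in range(17, 21):
        for d in range(4, length):
            design = make_spell(locus, edit, pbs_length=length,
                                deletion_position=d, u6_mode=False)
            assert intact_upstream_segment(design) == \
                build_pbs(locus, d - 1).bases


def test_spell_warns_outside_range_and_rejects_bad_position(locus, edit):
    design = make_spell(locus, edit, pbs_length=15, deletion_position=8,
                        u6_mode=False)
    assert any("recommended" in w for w in design.warnings)
    with pytest.raises(DesignError):
        make_spell(locus, edit, pbs_length=20, deletion_position=20)


# --------------------------------------------------------------------------
# scrambles

def test_scramble_homopolymer_segment_errors(rng):
    while True:
        locus = make_locus(rng)
        nick = locus.nick_index()
        ref = locus.reference.bases
        ref = ref[: nick - 20] + "TTTT" + ref[nick - 16 :]
        try:
            from spellpeg import TargetLocus, dna
            locus2 = TargetLocus(dna(ref), locus.protospacer_start, "+")
            break
        except DesignError:
            continue
    base = design_pegrna(locus2, simple_substitution(locus2), pbs_length=20,
                         u6_mode=False)
    assert base.pbs.bases[16:20] == "AAAA"
    with pytest.raises(DesignError):
        scramble_pbs_end(base, 17, seed=1)


def test_scramble_is_seed_deterministic_and_breaks_pairs(base20):
    s1 = scramble_pbs_end(base20, 13, seed=5)
    s2 = scramble_pbs_end(base20, 13, seed=5)
    assert s1.pbs == s2.pbs
    assert s1.pbs != base20.pbs
    cm = complementarity_map(s1)
    for pr in cm.pairs:
        if pr.pbs_position >= 13:
            assert not pr.is_watson_crick


def test_scramble_preserves_composition(rng):
    from collections import Counter

    checked = 0
    attempts = 0
    while checked < 200 and attempts < 2000:
        attempts += 1
        locus = make_locus(rng)
        base = design_pegrna(locus, simple_substitution(locus), pbs_length=20,
                             u6_mode=False)
        seed = int(rng.integers(0, 2**31))
        start = int(rng.integers(10, 18))
        try:
            scrambled = scramble_pbs_end(base, start, seed=seed)
        except DesignError:
            continue
        assert Counter(scrambled.pbs.bases) == Counter(base.pbs.bases)
        assert scrambled.pbs.bases[: start - 1] == base.pbs.bases[: start - 1]
        checked += 1
    assert checked == 200


# --------------------------------------------------------------------------
# combinations

def test_combo_deletion_plus_spacer_mismatch(base20):
    specs = [
        VariantSpec(VariantKind.PBS_DELETION, (13,), deletion_length=1),
        VariantSpec(VariantKind.SPACER_MISMATCH, (15,)),
    ]
    design = combine(base20, specs)
    assert len(design.pbs) == 19
    assert design.spacer_mismatches and design.spacer_mismatches[0].position == 15
    cm = complementarity_map(design)
    # register shifted downstream of the deletion: spacer position 16 unpaired
    assert 16 not in cm.covered_spacer_positions
    broken = [p for p in cm.pairs if p.spacer_position == 15]
    assert broken and not broken[0].is_watson_crick


def test_combo_identity_and_order_insensitivity(base20):
    assert combine(base20, []) is base20
    specs = [
        VariantSpec(VariantKind.SPACER_MISMATCH, (15,)),
        VariantSpec(VariantKind.PBS_DELETION, (13,), deletion_length=1),
    ]
    a = combine(base20, specs)
    b = combine(base20, specs[::-1])
    assert a.full_sequence == b.full_sequence


def test_combo_conflicting_specs_error(base20):
    specs = [
        VariantSpec(VariantKind.SPACER_MISMATCH, (15,)),
        VariantSpec(VariantKind.SPACER_MISMATCH, (15,)),
    ]
    with pytest.raises(DesignError, match="15"):
        combine(base20, specs)


def test_variant_frame_export(base20):
    vs = pbs_deletion_variants(base20, [12, 13], [1, 2])
    frame = variant_set_to_frame(vs)
    assert len(frame) == 4
    assert set(frame["kind"]) == {"pbs_deletion"}
    assert (frame["full_sequence"] != base20.full_sequence.bases).all()
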