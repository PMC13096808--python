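"""Alignment, windowed indel calling, edit detection, quantification
arithmetic, and gene-specific demultiplexing."""

import numpy as np
import pytest

from spellpeg import DesignError, EditSpec, dna
from spellpeg.ampquant import (
    AlignParams,
    AmpliconSpec,
    DemuxSpec,
    GeneMotifs,
    ReadCall,
    align_reads,
    call_read,
    call_reads,
    demux_gene_specific,
    quantify,
    quantify_sample_sheet,
    read_fastq,
    read_sam_alignments,
)
from spellpeg.simreads import IndelClass, ReadSimConfig, simulate_amplicon_reads, \
    write_fastq


@pytest.fixture
def amp(rng):
    return dna("".join(rng.choice(list("ACGT"), size=120)))


@pytest.fixture
def spec(amp):
    nick = 55
    ref_base = amp.bases[nick + 2]
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    return AmpliconSpec(amp, (nick,), EditSpec.substitution(3, ref_base, alt))


# --------------------------------------------------------------------------
# alignment

def test_reference_read_aligns_gap_free(spec):
    (aln,) = align_reads([("r0", spec.reference.bases)], spec)
    assert aln.aligned and aln.identity == 1.0 and aln.events == ()


def test_single_deletion_at_nick_is_located(spec):
    nick = spec.nick_sites[0]
    ref = spec.reference.bases
    read = ref[:nick] + ref[nick + 1 :]
    (aln,) = align_reads([("r0", read)], spec, AlignParams(fast_path=False))
    assert aln.aligned
    dels = [e for e in aln.events if e.kind == "del"]
    assert len(dels) == 1 and dels[0].length == 1
    # placement may slide within a repeat run; span must touch the nick
    assert abs(dels[0].position - nick) <= 2


def test_unrelated_read_is_excluded(spec, rng):
    junk = "".join(rng.choice(list("ACGT"), size=120))
    (aln,) = align_reads([("r0", junk)], spec)
    if aln.aligned:  # astronomically unlikely
        pytest.fail("random read should not align")
    assert aln.reason


def test_empty_input_errors(spec):
    with pytest.raises(DesignError):
        align_reads([], spec)


# --------------------------------------------------------------------------
# calling

def _perfect_edit_read(spec):
    ref = spec.reference.bases
    i = spec.edit_start
    e = spec.intended_edit
    return ref[:i] + e.alt_allele + ref[i + len(e.ref_allele):]


def test_intended_edit_read_flags(spec):
    read = _perfect_edit_read(spec)
    (aln,) = align_reads([("r0", read)], spec)
    call = call_read(aln, spec)
    assert call.has_intended_edit and not call.has_indel_in_window


def test_window_boundary_for_two_nt_deletion():
    """A 2-nt deletion starting at nick+2 touches the +/-2 window; at
    nick+3 it no longer intersects. A period-4 reference keeps short
    deletion placements unambiguous."""
    ref = "ACGT" * 30
    nick = 60
    amp = dna(ref)
    spec = AmpliconSpec(amp, (nick,), EditSpec.substitution(20, ref[nick + 19], "A"))
    for start, expected in ((nick + 2, True), (nick + 3, False)):
        read = ref[:start] + ref[start + 2 :]
        (aln,) = align_reads([("r0", read)], spec, AlignParams(fast_path=False))
        call = call_read(aln, spec)
        assert call.has_indel_in_window == expected, start


def test_error_inside_flank_defeats_edit_detection(spec):
    read = list(_perfect_edit_read(spec))
    i = spec.edit_start - 2  # inside the 5' flank
    read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
    (aln,) = align_reads([("r0", "".join(read))], spec)
    assert not call_read(aln, spec).has_intended_edit


def test_window_rule_is_shift_invariant(spec, rng):
    """Prepending a constant offset to reference and reads leaves calls
    unchanged."""
    pad = "".join(rng.choice(list("ACGT"), size=17))
    nick = spec.nick_sites[0]
    ref = spec.reference.bases
    shifted_spec = AmpliconSpec(
        dna(pad + ref), (nick + 17,), spec.intended_edit,
    )
    reads = [
        ("edit", _perfect_edit_read(spec)),
        ("del", ref[:nick] + ref[nick + 1 :]),
        ("wt", ref),
    ]
    calls = call_reads(align_reads(reads, spec), spec)
    shifted_reads = [(rid, pad + seq) for rid, seq in reads]
    shifted_calls = call_reads(
        align_reads(shifted_reads, shifted_spec), shifted_spec
    )
    for a, b in zip(calls, shifted_calls):
        assert (a.has_indel_in_window, a.has_intended_edit) == \
            (b.has_indel_in_window, b.has_intended_edit)


# --------------------------------------------------------------------------
# quantification arithmetic

def _mk_call(i, edit=False, indel=False):
    return ReadCall(f"r{i}", True, indel, (), edit)


def test_substitution_percentages(spec):
    calls = [_mk_call(i, edit=i < 1250) for i in range(10_000)]
    result = quantify(calls, spec)
    assert result.edit_pct == 12.5 and result.indel_pct == 0.0


def test_background_subtraction(spec):
    calls = [_mk_call(i, edit=i < 1250) for i in range(10_000)]
    control = [_mk_call(i, edit=i < 5) for i in range(1000)]
    result = quantify(calls, spec, control_calls=control)
    assert result.edit_pct_bgsub == pytest.approx(12.0)
    assert not result.negative_after_bgsub


def test_background_subtraction_is_linear(spec):
    sample = [_mk_call(i, edit=i < 30, indel=30 <= i < 40) for i in range(200)]
    control = [_mk_call(i, edit=i < 2, indel=2 <= i < 5) for i in range(100)]
    combined = quantify(sample, spec, control_calls=control)
    alone = quantify(sample, spec)
    ctrl = quantify(control, spec)
    assert combined.edit_pct_bgsub == pytest.approx(alone.edit_pct - ctrl.edit_pct)
    assert combined.indel_pct_bgsub == pytest.approx(
        alone.indel_pct - ctrl.indel_pct
    )


def test_negative_background_is_reported_not_floored(spec):
    sample = [_mk_call(i) for i in range(100)]
    control = [_mk_call(i, edit=i < 10) for i in range(100)]
    result = quantify(sample, spec, control_calls=control)
    assert result.edit_pct_bgsub == pytest.approx(-10.0)
    assert result.negative_after_bgsub


def test_transfection_normalization_and_bounds(spec):
    calls = [_mk_call(i, edit=i < 10) for i in range(100)]
    result = quantify(calls, spec, transfection_eff=0.5)
    assert result.edit_pct_norm == pytest.approx(20.0)
    with pytest.raises(DesignError):
        quantify(calls, spec, transfection_eff=1.5)
    with pytest.raises(DesignError):
        quantify(calls, spec, transfection_eff=0.0)


def test_insertion_edit_rules(amp):
    """For an indel-type intended edit, edit reads count even with their
    window indel, and the indel background excludes them."""
    nick = 55
    spec_ins = AmpliconSpec(amp, (nick,), EditSpec.insertion(1, "TAC"))
    ref = amp.bases
    ins_read = ref[:nick] + "TAC" + ref[nick:]
    del_read = ref[:nick] + ref[nick + 2 :]
    reads = [("ins", ins_read)] * 10 + [("del", del_read)] * 5 + [("wt", ref)] * 85
    calls = call_reads(align_reads(reads, spec_ins, AlignParams(fast_path=False)),
                       spec_ins)
    result = quantify(calls, spec_ins)
    assert result.edit_pct == pytest.approx(10.0)
    assert result.indel_pct == pytest.approx(5.0)


def test_substitution_edit_with_indel_is_not_counted(spec):
    calls = [_mk_call(0, edit=True, indel=True)] + \
        [_mk_call(i + 1) for i in range(99)]
    result = quantify(calls, spec)
    assert result.edit_pct == 0.0 and result.indel_pct == 1.0


# --------------------------------------------------------------------------
# SAM ingestion

def test_sam_alignments(tmp_path, spec):
    ref_name = "amplicon"
    nick = spec.nick_sites[0]
    sam = tmp_path / "reads.sam"
    ref_len = len(spec.reference)
    edit_read = _perfect_edit_read(spec)
    del_read = spec.reference.bases[: nick - 1] + spec.reference.bases[nick + 1 :]
    sam.write_text(
        f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{ref_name}\tLN:{ref_len}\n"
        f"r0\t0\t{ref_name}\t1\t60\t{ref_len}M\t*\t0\t0\t{edit_read}\t*\tNM:i:1\n"
        f"r1\t0\t{ref_name}\t1\t60\t{nick - 1}M2D{ref_len - nick - 1}M\t*\t0\t0\t"
        f"{del_read}\t*\tNM:i:2\n"
        f"r2\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
    )
    alns = read_sam_alignments(sam, spec)
    assert [a.aligned for a in alns] == [True, True, False]
    calls = call_reads(alns, spec)
    assert calls[0].has_intended_edit and not calls[0].has_indel_in_window
    assert calls[1].has_indel_in_window
    result = quantify(calls, spec)
    assert result.total_reads == 2  # unmapped read excluded


# --------------------------------------------------------------------------
# demultiplexing

def _demux_spec():
    return DemuxSpec({
        "geneA": GeneMotifs("ACGTAC", (0, 12), "GGATCC", (20, 32)),
        "geneB": GeneMotifs("TTGCAA", (0, 12), "CCTAGG", (20, 32)),
    })


def _read(m1, m2):
    return "XX".replace("X", "A") + m1 + "AAAAAAAAAAAA" + m2 + "AAAA"


def test_demux_assignment_chimeras_and_partition():
    demux = _demux_spec()
    a = ("a", "AA" + "ACGTAC" + "A" * 12 + "GGATCC" + "AAAA")
    b = ("b", "AA" + "TTGCAA" + "A" * 12 + "CCTAGG" + "AAAA")
    chimera = ("c", "AA" + "ACGTAC" + "A" * 12 + "CCTAGG" + "AAAA")
    nothing = ("n", "G" * 32)
    reads = [a] * 100 + [b] * 100 + [chimera] * 10 + [nothing]
    per_gene, excluded = demux_gene_specific(reads, demux)
    assert len(per_gene["geneA"]) == 100 and len(per_gene["geneB"]) == 100
    assert len(excluded) == 11
    chimera_rows = [r for r in excluded if "chimera" in r[2]]
    assert len(chimera_rows) == 10
    total = sum(len(v) for v in per_gene.values()) + len(excluded)
    assert total == len(reads)


def test_demux_config_validation():
    with pytest.raises(DesignError):
        DemuxSpec({"only": GeneMotifs("ACGTAC", (0, 12), "GGATCC", (20, 32))})
    with pytest.raises(DesignError):
        DemuxSpec({
            "a": GeneMotifs("ACGTAC", (0, 12), "GGATCC", (20, 32)),
            "b": GeneMotifs("ACGTAC", (0, 12), "GGATCC", (20, 32)),
        })
    with pytest.raises(DesignError):
        GeneMotifs("ACGTAC", (0, 12), "GGATCC", (10, 22))  # overlapping windows


# --------------------------------------------------------------------------
# sample sheet

def test_sample_sheet_pipeline(tmp_path, amp):
    import pandas as pd

    nick = 55
    ref_base = amp.bases[nick + 2]
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    edit = EditSpec.substitution(3, ref_base, alt)
    spec = AmpliconSpec(amp, (nick,), edit)
    cfg = ReadSimConfig(amp, nick, edit, 0.25, (), 0.0, 400, seed=9)
    reads, _ = simulate_amplicon_reads(cfg)
    write_fastq(reads, tmp_path / "sample.fastq")
    ctrl_cfg = ReadSimConfig(amp, nick, edit, 0.01, (), 0.0, 400, seed=10)
    ctrl_reads, _ = simulate_amplicon_reads(ctrl_cfg)
    write_fastq(ctrl_reads, tmp_path / "control.fastq")
    sheet = pd.DataFrame([
        {"sample": "ctrl", "fastq": "control.fastq", "control": "",
         "transfection_eff": ""},
        {"sample": "s1", "fastq": "sample.fastq", "control": "ctrl",
         "transfection_eff": "0.5"},
    ])
    table = quantify_sample_sheet(sheet, spec, base_dir=tmp_path)
    row = table.set_index("sample").loc["s1"]
    assert row["edit_pct"] == pytest.approx(25.0)
    assert row["edit_pct_bgsub"] == pytest.approx(24.0)
    assert row["edit_pct_norm"] == pytest.approx(48.0)
    with pytest.raises(DesignError):
        quantify_sample_sheet(
            sheet.assign(control=["", "missing"]), spec, base_dir=tmp_path
        )
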