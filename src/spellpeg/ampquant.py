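"""Amplicon-sequencing quantification of prime-editing outcomes.

Pipeline: global alignment of each read to the reference amplicon ->
per-read calls (windowed indels around the nick sites; flank-anchored
intended-edit detection) -> per-sample percentages with background
subtraction and transfection normalization. Gene-specific two-motif
demultiplexing handles paralogous amplicons and PCR template-switch
chimeras.

Rules implemented:

* aligned reads are the denominator ("total reads"); unalignable reads
  (identity below the configured threshold) are flagged and excluded;
* indels are searched at +/- ``indel_window`` (default 2) bp around every
  nick/cut site; an event counts when its reference span *intersects* the
  closed window (the conservative reading; configurable semantics are
  deliberately not offered — the span rule is documented and fixed);
* an intended edit is an exact occurrence, in the read, of the edited
  allele flanked by ``edit_window_flank`` (default 5) exactly matching
  reference nucleotides on each side;
* substitution edits count reads with the edit and no window indel;
  insertion/deletion edits count all intended-edit reads, and the indel
  background then counts only window-indel reads that are not the intended
  edit;
* background percentages from an untransfected control are subtracted
  as-is (negative results are reported, flagged, never floored), and the
  transfection-efficiency division is applied after subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .seqcore import Alphabet, DesignError, NucSeq, SequenceError
from .pegdesign import EditSpec, EditType


@dataclass(frozen=True)
class AlignParams:
    """Global affine-gap alignment parameters (all configurable)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    min_identity: float = 0.70
    fast_path: bool = True  # gap-free shortcut for equal-length reads


DEFAULT_ALIGN = AlignParams()


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon, nick coordinates, and the intended edit.

    ``nick_sites`` are 0-based between-base coordinates on the reference
    (the pegRNA nick first, an optional second nick after it); the
    ``intended_edit`` is anchored to the first nick site via its
    ``nick_distance``.
    """

    reference: NucSeq
    nick_sites: tuple[int, ...]
    intended_edit: EditSpec
    edit_window_flank: int = 5
    indel_window: int = 2

    def __post_init__(self) -> None:
        if self.reference.alphabet is not Alphabet.DNA:
            raise SequenceError("reference must be DNA")
        if not self.nick_sites:
            raise DesignError("at least one nick site is required")
        for n in self.nick_sites:
            if not 0 < n < len(self.reference):
                raise DesignError(f"nick site {n} outside the reference")
        if self.edit_window_flank < 1:
            raise DesignError("edit_window_flank must be >= 1")
        self.edited_motif  # validates allele vs reference

    @property
    def edit_start(self) -> int:
        """Reference index of the first edited base."""
        return self.nick_sites[0] + self.intended_edit.nick_distance - 1

    @property
    def edited_motif(self) -> str:
        """The edited allele with its exactly matching reference flanks."""
        ref = self.reference.bases
        e = self.intended_edit
        i = self.edit_start
        f = self.edit_window_flank
        if i - f < 0:
            raise DesignError("edit too close to the amplicon start for flanks")
        left = ref[i - f : i]
        if e.edit_type is EditType.INSERTION:
            right = ref[i : i + f]
            core = e.alt_allele
        else:
            if ref[i : i + len(e.ref_allele)] != e.ref_allele:
                raise DesignError("intended_edit ref_allele mismatches the reference")
            right = ref[i + len(e.ref_allele) : i + len(e.ref_allele) + f]
            core = e.alt_allele  # empty for deletions
        if len(right) < f:
            raise DesignError("edit too close to the amplicon end for flanks")
        return left + core + right


@dataclass(frozen=True)
class IndelEvent:
    position: int  # reference coordinate: base index (del) / between-base (ins)
    kind: str  # 'ins' | 'del'
    length: int

    @property
    def span(self) -> tuple[int, int]:
        """Between-base reference span touched by the event."""
        if self.kind == "del":
            return (self.position, self.position + self.length)
        return (self.position, self.position)


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    seq: str
    aligned: bool
    identity: float
    events: tuple[IndelEvent, ...] = ()
    reason: str = ""


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    aligned: bool
    has_indel_in_window: bool
    indel_events: tuple[IndelEvent, ...]
    has_intended_edit: bool


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _events_from_alignment(aln, ref_len: int, read_len: int):
    t_blocks, q_blocks = aln.aligned
    events: list[IndelEvent] = []
    matches = 0
    columns = 0
    prev_t, prev_q = 0, 0
    target, query = str(aln.target), str(aln.query)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        dt, dq = ts - prev_t, qs - prev_q
        if dt:
            events.append(IndelEvent(int(prev_t), "del", int(dt)))
            columns += dt
        if dq:
            events.append(IndelEvent(int(ts), "ins", int(dq)))
            columns += dq
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
        columns += te - ts
        prev_t, prev_q = te, qe
    dt, dq = ref_len - prev_t, read_len - prev_q
    if dt:
        events.append(IndelEvent(int(prev_t), "del", int(dt)))
        columns += dt
    if dq:
        events.append(IndelEvent(ref_len, "ins", int(dq)))
        columns += dq
    identity = matches / columns if columns else 0.0
    return tuple(events), identity


def align_reads(
    reads: list[tuple[str, str]],
    spec: AmpliconSpec,
    params: AlignParams = DEFAULT_ALIGN,
) -> list[AlignedRead]:
    """Globally align reads to the reference amplicon.

    Equal-length reads whose gap-free identity already clears the
    threshold skip the dynamic program (``params.fast_path``); everything
    else gets a full affine-gap global alignment. Reads below
    ``min_identity`` are flagged unaligned and excluded from totals.
    """
    if not reads:
        raise DesignError("no reads to align")
    ref = spec.reference.bases
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    aligner = _make_aligner(params)
    out: list[AlignedRead] = []
    for read_id, seq in reads:
        if params.fast_path and len(seq) == len(ref):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            identity = float((arr == ref_arr).mean())
            if identity >= params.min_identity:
                out.append(AlignedRead(read_id, seq, True, identity))
                continue
        elif params.fast_path and len(seq) < len(ref):
            # truncated read matching a reference prefix: gap-free + end gap
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            identity = float((arr == ref_arr[: len(arr)]).mean())
            if identity >= 0.99:
                events = (IndelEvent(len(seq), "del", len(ref) - len(seq)),)
                out.append(AlignedRead(read_id, seq, True, identity, events))
                continue
        aln = aligner.align(ref, seq)[0]
        events, identity = _events_from_alignment(aln, len(ref), len(seq))
        if identity < params.min_identity:
            out.append(
                AlignedRead(read_id, seq, False, identity, (),
                            reason="identity below threshold")
            )
        else:
            out.append(AlignedRead(read_id, seq, True, identity, events))
    return out


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not reads:
        raise SequenceError(f"no FASTQ records in {path}")
    return reads


def read_sam_alignments(
    path: str | Path, spec: AmpliconSpec
) -> list[AlignedRead]:
    """Ingest pre-aligned reads from a (text) SAM file, bypassing the
    internal aligner; CIGAR I/D operations become indel events."""
    import pysam

    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            seq = rec.query_sequence or ""
            if rec.is_unmapped:
                out.append(AlignedRead(rec.query_name, seq, False, 0.0, (),
                                       reason="unmapped in SAM"))
                continue
            events: list[IndelEvent] = []
            ref_pos = rec.reference_start
            matched = 0
            columns = 0
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    ref_pos += length
                    matched += length
                    columns += length
                elif op == 1:  # I
                    events.append(IndelEvent(ref_pos, "ins", length))
                    columns += length
                elif op == 2:  # D
                    events.append(IndelEvent(ref_pos, "del", length))
                    ref_pos += length
                    columns += length
                elif op == 4:  # soft clip
                    columns += length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            identity = (matched - nm) / columns if columns else 0.0
            out.append(
                AlignedRead(rec.query_name, seq, True, identity, tuple(events))
            )
    if not out:
        raise SequenceError(f"no records in SAM {path}")
    return out


def _window_hit(event: IndelEvent, nick: int, w: int) -> bool:
    s, e = event.span
    return s <= nick + w and e >= nick - w


def call_read(aln: AlignedRead, spec: AmpliconSpec) -> ReadCall:
    """Classify one aligned read: windowed indel flag + intended edit."""
    if not aln.aligned:
        return ReadCall(aln.read_id, False, False, (), False)
    w = spec.indel_window
    has_indel = any(
        _window_hit(ev, nick, w) for ev in aln.events for nick in spec.nick_sites
    )
    has_edit = spec.edited_motif in aln.seq
    return ReadCall(aln.read_id, True, has_indel, aln.events, has_edit)


def call_reads(
    alignments: list[AlignedRead], spec: AmpliconSpec
) -> list[ReadCall]:
    return [call_read(a, spec) for a in alignments]


@dataclass(frozen=True)
class QuantResult:
    total_reads: int
    edit_pct: float
    indel_pct: float
    edit_pct_bgsub: float | None = None
    indel_pct_bgsub: float | None = None
    edit_pct_norm: float | None = None
    denominators_used: dict = field(default_factory=dict)
    negative_after_bgsub: bool = False

    def to_row(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "edit_pct": self.edit_pct,
            "indel_pct": self.indel_pct,
            "edit_pct_bgsub": self.edit_pct_bgsub,
            "indel_pct_bgsub": self.indel_pct_bgsub,
            "edit_pct_norm": self.edit_pct_norm,
            "negative_after_bgsub": self.negative_after_bgsub,
        }


def quantify(
    calls: list[ReadCall],
    spec: AmpliconSpec,
    control_calls: list[ReadCall] | None = None,
    transfection_eff: float | None = None,
) -> QuantResult:
    """Per-sample edit/indel percentages with the documented denominators.

    Aligned reads are the total. For a substitution edit the edit count
    requires no window indel; for insertion/deletion edits every
    intended-edit read counts and the indel percentage excludes them.
    Background percentages (control sample) are subtracted componentwise;
    the transfection-efficiency division comes after subtraction.
    """
    aligned = [c for c in calls if c.aligned]
    total = len(aligned)
    if total < 1:
        raise DesignError("no aligned reads to quantify")
    n_edit_any = sum(c.has_intended_edit for c in aligned)
    n_window = sum(c.has_indel_in_window for c in aligned)
    is_indel_edit = spec.intended_edit.edit_type in (
        EditType.INSERTION, EditType.DELETION
    )
    if is_indel_edit:
        n_edit = n_edit_any
        n_indel = sum(
            c.has_indel_in_window and not c.has_intended_edit for c in aligned
        )
    else:
        n_edit = sum(
            c.has_intended_edit and not c.has_indel_in_window for c in aligned
        )
        n_indel = n_window
    edit_pct = 100.0 * n_edit / total
    indel_pct = 100.0 * n_indel / total
    denominators = {
        "total_reads": total,
        "n_intended_any": n_edit_any,
        "n_edit_counted": n_edit,
        "n_window_indel": n_window,
        "n_indel_counted": n_indel,
        "edit_rule": "indel-type" if is_indel_edit else "substitution",
    }
    edit_bg = indel_bg = None
    negative = False
    if control_calls is not None:
        control = quantify(control_calls, spec)
        edit_bg = edit_pct - control.edit_pct
        indel_bg = indel_pct - control.indel_pct
        negative = edit_bg < 0 or indel_bg < 0
        denominators["control_total_reads"] = control.total_reads
    norm = None
    if transfection_eff is not None:
        if not 0 < transfection_eff <= 1:
            raise DesignError("transfection efficiency must be in (0, 1]")
        norm = (edit_bg if edit_bg is not None else edit_pct) / transfection_eff
    return QuantResult(
        total_reads=total,
        edit_pct=edit_pct,
        indel_pct=indel_pct,
        edit_pct_bgsub=edit_bg,
        indel_pct_bgsub=indel_bg,
        edit_pct_norm=norm,
        denominators_used=denominators,
        negative_after_bgsub=negative,
    )


# --------------------------------------------------------------------------
# gene-specific demultiplexing (paralogous amplicons, chimera exclusion)

@dataclass(frozen=True)
class GeneMotifs:
    """Two gene-specific motifs at different positions of one amplicon;
    each window is a half-open (start, end) slice of the read in which the
    motif must occur."""

    motif_1: str
    window_1: tuple[int, int]
    motif_2: str
    window_2: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif_1", self.motif_1.upper())
        object.__setattr__(self, "motif_2", self.motif_2.upper())
        w1, w2 = self.window_1, self.window_2
        if not (w1[0] < w1[1] and w2[0] < w2[1]):
            raise DesignError("motif windows must be non-empty (start < end)")
        if not (w1[1] <= w2[0] or w2[1] <= w1[0]):
            raise DesignError("the two motifs must sit at different positions")


@dataclass(frozen=True)
class DemuxSpec:
    genes: dict[str, GeneMotifs]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise DesignError("demultiplexing needs at least two gene specs")
        seen = {}
        for name, gm in self.genes.items():
            key = (gm.motif_1, gm.motif_2)
            if key in seen:
                raise DesignError(
                    f"genes {seen[key]!r} and {name!r} share both motifs; "
                    "assignment would be ambiguous"
                )
            seen[key] = name


def _slot_hits(seq: str, gm: GeneMotifs) -> tuple[bool, bool]:
    return (
        gm.motif_1 in seq[gm.window_1[0] : gm.window_1[1]],
        gm.motif_2 in seq[gm.window_2[0] : gm.window_2[1]],
    )


def demux_gene_specific(
    reads: list[tuple[str, str]], demux: DemuxSpec
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str, str]]]:
    """Assign each read to the gene whose BOTH motifs it carries.

    Reads carrying motifs of different genes (template-switch chimeras or
    mispriming) and reads matching no complete motif pair are excluded,
    with a reason. Returns ``(per_gene_reads, excluded)`` where excluded
    rows are (read_id, seq, reason).
    """
    per_gene: dict[str, list[tuple[str, str]]] = {g: [] for g in demux.genes}
    excluded: list[tuple[str, str, str]] = []
    for read_id, seq in reads:
        full = []
        partial_genes = set()
        for gene, gm in demux.genes.items():
            h1, h2 = _slot_hits(seq, gm)
            if h1 and h2:
                full.append(gene)
            elif h1 or h2:
                partial_genes.add(gene)
        if len(full) == 1:
            per_gene[full[0]].append((read_id, seq))
        elif len(full) > 1:
            excluded.append((read_id, seq, "ambiguous: full match to "
                             + ",".join(sorted(full))))
        elif len(partial_genes) >= 2:
            excluded.append((read_id, seq, "chimera: motifs of "
                             + ",".join(sorted(partial_genes))))
        elif partial_genes:
            excluded.append((read_id, seq,
                             f"partial: single motif of {partial_genes.pop()}"))
        else:
            excluded.append((read_id, seq, "no gene-specific motif"))
    return per_gene, excluded


# --------------------------------------------------------------------------
# sample-sheet driven quantification

def quantify_sample_sheet(
    sheet: pd.DataFrame | str | Path,
    spec: AmpliconSpec,
    params: AlignParams = DEFAULT_ALIGN,
    base_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full pipeline for a sample sheet.

    The sheet (TSV path or DataFrame) needs columns ``sample``, ``fastq``,
    ``control`` (control sample id, empty for none) and
    ``transfection_eff`` (empty for none). Controls are processed first and
    their percentages subtracted from the samples referencing them.
    """
    if not isinstance(sheet, pd.DataFrame):
        sheet = pd.read_csv(sheet, sep="\t", dtype=str)
    required = {"sample", "fastq", "control", "transfection_eff"}
    missing = required - set(sheet.columns)
    if missing:
        raise DesignError(f"sample sheet missing column(s): {sorted(missing)}")
    base = Path(base_dir) if base_dir else Path(".")
    calls_by_sample: dict[str, list[ReadCall]] = {}
    for _, row in sheet.iterrows():
        reads = read_fastq(base / row["fastq"])
        calls_by_sample[row["sample"]] = call_reads(
            align_reads(reads, spec, params), spec
        )
    rows = []
    for _, row in sheet.iterrows():
        control_id = (row["control"] or "") if isinstance(row["control"], str) else ""
        control_calls = None
        if control_id:
            if control_id not in calls_by_sample:
                raise DesignError(
                    f"sample {row['sample']!r} references unknown control "
                    f"{control_id!r}"
                )
            control_calls = calls_by_sample[control_id]
        te_raw = row["transfection_eff"]
        te = float(te_raw) if isinstance(te_raw, str) and te_raw else None
        result = quantify(
            calls_by_sample[row["sample"]], spec, control_calls, te
        )
        rows.append({"sample": row["sample"], **result.to_row()})
    return pd.DataFrame(rows)
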