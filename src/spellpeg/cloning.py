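"""Wet-lab encodings of a PegDesign: Golden Gate linker oligos and T7
in-vitro-transcription template primers.

Two-step Golden Gate scheme: the spacer linker is cloned first (BpiI), the
RTT-PBS extension linker second (BsmBI). Overhang sequences are a
CONVENTION shipped as a documented default — the cited backbones do not
publish them — so verify ``OverhangConfig`` against your own plasmid before
ordering. All oligo output is DNA (RNA parts back-transcribed U->T).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .seqcore import DesignError, NucSeq, dna, revcomp, to_dna
from .pegdesign import PegDesign

#: Type IIS recognition sites used by the two cloning steps.
ENZYME_SITES = {"BpiI": "GAAGAC", "BsmBI": "CGTCTC"}


@dataclass(frozen=True)
class OverhangConfig:
    """4-nt sticky-end overhangs for the two Golden Gate steps.

    The defaults follow the common U6-sgRNA cloning convention
    (CACC/AAAC for the spacer) and a complementary pair for the extension
    linker; they are a convention, verify against your backbone.
    """

    spacer_top_overhang: str = "CACC"
    spacer_bottom_overhang: str = "AAAC"
    extension_top_overhang: str = "GTGC"
    extension_bottom_overhang: str = "CGCG"
    spacer_enzyme: str = "BpiI"
    extension_enzyme: str = "BsmBI"

    def __post_init__(self) -> None:
        for name in (
            "spacer_top_overhang", "spacer_bottom_overhang",
            "extension_top_overhang", "extension_bottom_overhang",
        ):
            oh = getattr(self, name).upper()
            object.__setattr__(self, name, oh)
            if len(oh) != 4 or set(oh) - set("ACGT"):
                raise DesignError(f"{name} must be a 4-nt DNA overhang: {oh!r}")
        for top, bottom in (
            (self.spacer_top_overhang, self.spacer_bottom_overhang),
            (self.extension_top_overhang, self.extension_bottom_overhang),
        ):
            if top == str(revcomp(dna(bottom))):
                raise DesignError(
                    f"top/bottom overhangs {top}/{bottom} are complementary; "
                    "the linker would self-ligate"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OverhangConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


DEFAULT_OVERHANGS = OverhangConfig()


@dataclass(frozen=True)
class OligoPair:
    """An annealed linker: two single-stranded DNA oligos sharing a
    double-stranded core with 4-nt 5' protrusions per the config."""

    top: NucSeq
    bottom: NucSeq
    anneal_core: NucSeq

    def __post_init__(self) -> None:
        core = self.top.bases[4:]
        if self.bottom.bases[4:] != str(revcomp(dna(core))):
            raise DesignError("bottom core is not the reverse complement of top")


def _site_warnings(insert: str, enzyme: str) -> list[str]:
    site = ENZYME_SITES.get(enzyme)
    if site is None:
        return []
    warnings = []
    if site in insert or str(revcomp(dna(site))) in insert:
        warnings.append(
            f"insert contains a {enzyme} recognition site ({site}); the "
            "Golden Gate reaction may recut the product"
        )
    return warnings


def spacer_linker_oligos(
    design: PegDesign, cfg: OverhangConfig = DEFAULT_OVERHANGS
) -> tuple[OligoPair, list[str]]:
    """Spacer-step linker: top = overhang + spacer (DNA), bottom = overhang
    + revcomp. A 21G spacer is encoded verbatim including the appended G."""
    core = to_dna(design.spacer).bases
    top = dna(cfg.spacer_top_overhang + core)
    bottom = dna(cfg.spacer_bottom_overhang + str(revcomp(dna(core))))
    return OligoPair(top, bottom, dna(core)), _site_warnings(core, cfg.spacer_enzyme)


def extension_linker_oligos(
    design: PegDesign,
    cfg: OverhangConfig = DEFAULT_OVERHANGS,
    include_end_motif: bool = False,
) -> tuple[OligoPair, list[str]]:
    """Extension-step linker encoding RTT+PBS (+ 3' motif when the backbone
    lacks one). Modified PBSs are encoded verbatim — no silent repair."""
    core = to_dna(design.rtt).bases + to_dna(design.pbs).bases
    if include_end_motif:
        if design.end_motif is None:
            raise DesignError("design has no end motif to include")
        core += to_dna(design.end_motif).bases
    top = dna(cfg.extension_top_overhang + core)
    bottom = dna(cfg.extension_bottom_overhang + str(revcomp(dna(core))))
    return OligoPair(top, bottom, dna(core)), _site_warnings(
        core, cfg.extension_enzyme
    )


def simulate_golden_gate(
    spacer_pair: OligoPair,
    extension_pair: OligoPair,
    scaffold: NucSeq,
    end_motif: NucSeq | None = None,
) -> NucSeq:
    """In-silico two-step assembly into a virtual backbone.

    Ligation consumes the overhangs (they pair with the backbone's sticky
    ends); the reconstructed transcribed region is
    spacer + scaffold + rtt + pbs (+ motif), DNA sense strand.
    """
    seq = (
        spacer_pair.anneal_core.bases
        + to_dna(scaffold).bases
        + extension_pair.anneal_core.bases
    )
    if end_motif is not None:
        seq += to_dna(end_motif).bases
    return dna(seq)


DEFAULT_T7_PROMOTER = dna("TAATACGACTCACTATA")


def t7_ivt_template_primer(
    design: PegDesign,
    t7_promoter: NucSeq = DEFAULT_T7_PROMOTER,
    anneal_len: int = 20,
) -> tuple[NucSeq, list[str]]:
    """Forward PCR primer for building a T7 transcription template:
    promoter + the DNA of the design's first ``anneal_len`` nucleotides.

    T7 initiates most efficiently on G; a non-G first transcribed base
    draws a warning (U6-style designs always start with G)."""
    full = design.full_sequence
    if anneal_len > len(full):
        raise DesignError("anneal_len exceeds the design length")
    warnings = []
    if full.bases[0] != "G":
        warnings.append(
            "first transcribed base is not G: T7 initiation may be inefficient"
        )
    primer = dna(t7_promoter.bases + to_dna(design.full_sequence).bases[:anneal_len])
    return primer, warnings


def oligo_order_sheet(
    named_pairs: list[tuple[str, OligoPair]]
) -> pd.DataFrame:
    """Order-sheet table: one row per single-stranded oligo."""
    rows = []
    for name, pair in named_pairs:
        rows.append({"name": f"{name}_top", "sequence": pair.top.bases,
                     "length": len(pair.top)})
        rows.append({"name": f"{name}_bottom", "sequence": pair.bottom.bases,
                     "length": len(pair.bottom)})
    return pd.DataFrame(rows, columns=["name", "sequence", "length"])
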