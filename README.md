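# spellpeg

Prime editing installs a programmed change at a genomic site using a pegRNA:
a guide RNA whose 3′ end is extended with a reverse-transcription template
(RTT) and a primer binding site (PBS). Because the PBS is copied from the
protospacer region, it is intramolecularly complementary to the spacer, and
that spacer:PBS duplex inhibits editing — particularly with long PBSs.
`spellpeg` is a toolkit for designing pegRNAs around this constraint:

* explicit **complementarity-register geometry** — with the nick 3 nt from
  the PAM, a PBS of length *L* pairs spacer positions 4 … min(20, *L*+3), so
  the spacer:PBS duplex saturates at a 17-nt PBS and PBS nucleotides 18–20
  gain no spacer partner;
* **variant generation** that weakens the duplex: spacer mismatches
  (transitions/transversions with placement warnings), PBS mismatches,
  1–4-nt PBS deletions, PBS-end scrambles, and combinations;
* **SPELL pegRNAs** (Streamlined Prime Editing with fixed-Length PBS
  Leverage): a 17–20-nt PBS carrying a single-nucleotide deletion (default:
  position 13 of a 20-nt PBS, leaving a 12-nt intact 5′ segment plus a
  register-shifted 3′ segment) — a fixed-length design that avoids per-target
  PBS-length optimization;
* **PBS:non-target-strand thermodynamics** — nearest-neighbor Tm and ΔG(37 °C)
  with a bundled, citable RNA/DNA parameter table, ranked against the
  "Tm near 37 °C" design guideline;
* **wet-lab encodings** — two-step Golden Gate (BpiI/BsmBI convention) linker
  oligos and T7 in-vitro-transcription template primers;
* an **amplicon-sequencing quantifier** — global affine alignment, indels
  searched at ±2 bp around the nick sites, intended edits detected as the
  edited allele with 5+5 exactly matching flanks, aligned reads as the
  denominator, untransfected-background subtraction, transfection
  normalization, and two-motif gene-specific demultiplexing with chimera
  exclusion;
* a **synthetic read simulator** with exact class counts and a truth table,
  so every quantification stage is testable without sequencing data.

## Worked example

```python
import numpy as np
from spellpeg import (TargetLocus, EditSpec, design_report,
                      complementarity_map, dna)
from spellpeg.variants import make_spell, intact_upstream_segment

rng = np.random.default_rng(7)
ref = ("".join(rng.choice(list("ACGT"), 30))
       + "".join(rng.choice(list("ACGT"), 20)) + "AGG"
       + "".join(rng.choice(list("ACGT"), 30)))
locus = TargetLocus(dna(ref), protospacer_start=30, strand="+")
edit = EditSpec.substitution(nick_distance=1, ref="A", alt="G")

print(design_report(locus, edit, [7, 10, 13, 17, 20], u6_mode=False))
```

```
 pbs_length         pbs_sequence  tm_celsius  delta_g_kcal_per_mol  n_paired covered_spacer_positions
          7              UCAUAUG   -9.962547             -1.212644         7                     4-10
         10           UCAUAUGAGC   20.087797             -6.007773        10                     4-13
         13        UCAUAUGAGCCAA   33.218552             -8.999338        13                     4-16
         17    UCAUAUGAGCCAAACCC   48.521032            -14.933574        17                     4-20
         20 UCAUAUGAGCCAAACCCCGG   57.195492            -20.610488        17                     4-20
```

One row per candidate PBS length: the PBS sequence (5′→3′, RNA), the
two-state Tm and ΔG(37 °C) of its duplex with the non-target strand, the
number of Watson–Crick spacer:PBS pairs, and the spacer positions covered.
Here the 13-nt PBS sits closest to the 37 °C guideline; pairing saturates at
17 (the 20-nt PBS still pairs only 17 spacer positions).

```python
spell = make_spell(locus, edit)                # PBS20 with a deletion at 13
print(spell.pbs, intact_upstream_segment(spell),
      complementarity_map(spell).n_paired)
# UCAUAUGAGCCAACCCCGG  UCAUAUGAGCCA  16
```

The SPELL PBS is 19 nt: a 12-nt intact 5′ segment (identical to the plain
12-nt PBS) plus a 3′ segment whose register is shifted by one, leaving
spacer position 16 unpaired.

End-to-end quantification on simulated reads (10,000 reads, 12.5% intended
substitution edits, 4% indels around the nick, no sequencing error) returns
`edit_pct = 12.5` and `indel_pct = 4.0` exactly; the same pipeline is
exposed on the command line:

```sh
spellpeg simulate --reference amp.fa --nick 60 \
    --edit-type substitution --nick-distance 3 --ref C --alt T \
    --edit-fraction 0.125 --indel 0:del:2:0.04 --n-reads 10000 --seed 1
spellpeg quantify --reference amp.fa --nick 60 \
    --edit-type substitution --nick-distance 3 --ref C --alt T \
    --fastq sim_out/reads.fastq
```

Other subcommands: `design` (per-PBS-length report + FASTA), `variants`
(mismatch/deletion grids as TSV + FASTA), `oligos` (Golden Gate order
sheet + T7 primer), `aggregate` (efficiency-table dedupe and PBS-length
summaries).

## Layout

- `spellpeg.seqcore` — sequence primitives, substitution classes, protospacer/PAM scanning, FASTA I/O
- `spellpeg.pegdesign` — locus/edit frames, spacer/PBS/RTT builders, complementarity register, design report
- `spellpeg.thermo` — nearest-neighbor duplex Tm/ΔG (bundled parameter tables)
- `spellpeg.variants` — mismatch/deletion/scramble/SPELL/combination variant sets
- `spellpeg.cloning` — Golden Gate linker oligos, in-silico assembly, T7 IVT primers
- `spellpeg.simreads` — deterministic amplicon-read simulator with truth tables
- `spellpeg.ampquant` — alignment, windowed indel calls, edit detection, quantification, demultiplexing
- `spellpeg.aggregate` — efficiency-table dedupe, PBS-length summaries, fold changes, Welch test
- `spellpeg.cli` — the `spellpeg` command

See `docs/methods.md` for the models, conventions and numerical choices.
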