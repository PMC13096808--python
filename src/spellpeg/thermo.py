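"""Nearest-neighbor duplex thermodynamics for the PBS:non-target-strand duplex.

A two-state model: total dH/dS are summed over Watson-Crick nearest-neighbor
stacks plus a duplex-initiation term, the entropy is salt-corrected
(SantaLucia 1998 unified correction, 0.368 * N_stacks * ln[Na+]), and

    Tm = dH / (dS_corrected + R ln(C_T / 4)) - 273.15
    dG(37 C) = dH - 310.15 * dS_corrected / 1000

Parameter tables are data, not code: they ship in ``data/nn_params.json``
with their citations, and every report records which table and conditions
produced it. Mismatched positions contribute no stacks (both flanking
stacks are skipped) and are counted in the report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .seqcore import Alphabet, DesignError, NucSeq, SequenceError

R_CAL = 1.98720  # gas constant, cal/(mol K)
T37_K = 310.15

#: RNA base -> the DNA base it pairs with (Watson-Crick).
_RNA_DNA_PAIR = {"A": "T", "U": "A", "G": "C", "C": "G"}
_RNA_RNA_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _load_tables() -> dict:
    with resources.files("spellpeg.data").joinpath("nn_params.json").open() as fh:
        return json.load(fh)


_TABLES = _load_tables()

DEFAULT_PARAMETER_SET = "rna_dna_sugimoto_1995"


def available_parameter_sets() -> list[str]:
    return sorted(_TABLES)


@dataclass(frozen=True)
class ThermoConfig:
    """Conditions for the two-state duplex calculation.

    Defaults: 50 mM monovalent salt, 250 nM total strand concentration,
    non-self-complementary duplex.
    """

    parameter_set_id: str = DEFAULT_PARAMETER_SET
    salt_mM: float = 50.0
    strand_conc_nM: float = 250.0


DEFAULT_THERMO = ThermoConfig()


@dataclass(frozen=True)
class DuplexReport:
    tm_celsius: float
    delta_g_kcal_per_mol: float
    parameter_set_id: str
    salt_mM: float
    strand_conc_nM: float
    n_pairs: int
    n_mismatches: int


def duplex_tm(
    pbs: NucSeq, template: NucSeq, config: ThermoConfig = DEFAULT_THERMO
) -> DuplexReport:
    """Two-state Tm and dG(37 C) of an antiparallel duplex.

    ``pbs`` is the RNA strand 5'->3' and ``template`` the strand it anneals
    to, also 5'->3' (so ``pbs[0]`` pairs ``template[-1]``). The two must have
    equal length; non-Watson-Crick positions are tolerated but contribute no
    nearest-neighbor stacks and are reported.
    """
    if pbs.alphabet is not Alphabet.RNA:
        raise SequenceError("the probe strand must be RNA")
    if len(pbs) != len(template):
        raise DesignError("paired region must have equal strand lengths")
    if len(pbs) < 2:
        raise DesignError("duplex shorter than 2 bp has no stacks")
    try:
        table = _TABLES[config.parameter_set_id]
    except KeyError:
        raise DesignError(
            f"unknown parameter set {config.parameter_set_id!r}; "
            f"available: {available_parameter_sets()}"
        ) from None

    pair_of = (
        _RNA_RNA_PAIR if table["duplex_type"] == "RNA/RNA" else _RNA_DNA_PAIR
    )
    rev_template = template.bases[::-1]
    is_wc = [pair_of[b] == t for b, t in zip(pbs.bases, rev_template)]
    n_mismatches = len(is_wc) - sum(is_wc)

    stacks = table["stacks"]
    dh = table["initiation"]["dH"]
    ds = table["initiation"]["dS"]
    n_stacks = 0
    for i in range(len(pbs) - 1):
        if is_wc[i] and is_wc[i + 1]:
            entry = stacks[pbs.bases[i : i + 2]]
            dh += entry["dH"]
            ds += entry["dS"]
            n_stacks += 1
    if n_stacks == 0:
        raise DesignError("no Watson-Crick stacks in the given register")

    ds_corr = ds + 0.368 * n_stacks * math.log(config.salt_mM / 1000.0)
    ct = config.strand_conc_nM * 1e-9
    tm = dh * 1000.0 / (ds_corr + R_CAL * math.log(ct / 4.0)) - 273.15
    dg37 = dh - T37_K * ds_corr / 1000.0
    return DuplexReport(
        tm_celsius=tm,
        delta_g_kcal_per_mol=dg37,
        parameter_set_id=config.parameter_set_id,
        salt_mM=config.salt_mM,
        strand_conc_nM=config.strand_conc_nM,
        n_pairs=len(pbs),
        n_mismatches=n_mismatches,
    )
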