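{
  "rna_dna_sugimoto_1995": {
    "citation": "Sugimoto N. et al. (1995) Thermodynamic parameters to predict stability of RNA/DNA hybrid duplexes. Biochemistry 34:11211-11216.",
    "duplex_type": "RNA/DNA",
    "comment": "Keys are RNA dinucleotides 5'->3', paired with the complementary antiparallel DNA. dH in kcal/mol, dS in cal/(mol K).",
    "initiation": {"dH": 1.9, "dS": -3.9},
    "stacks": {
      "AA": {"dH": -7.8, "dS": -21.9},
      "AC": {"dH": -5.9, "dS": -12.3},
      "AG": {"dH": -9.1, "dS": -23.5},
      "AU": {"dH": -8.3, "dS": -23.9},
      "CA": {"dH": -9.0, "dS": -26.1},
      "CC": {"dH": -9.3, "dS": -23.2},
      "CG": {"dH": -16.3, "dS": -47.1},
      "CU": {"dH": -7.0, "dS": -19.7},
      "GA": {"dH": -5.5, "dS": -13.5},
      "GC": {"dH": -8.0, "dS": -17.1},
      "GG": {"dH": -12.8, "dS": -31.9},
      "GU": {"dH": -7.8, "dS": -21.6},
      "UA": {"dH": -7.8, "dS": -23.2},
      "UC": {"dH": -8.6, "dS": -22.9},
      "UG": {"dH": -10.4, "dS": -28.4},
      "UU": {"dH": -11.5, "dS": -36.4}
    }
  },
  "rna_rna_xia_1998": {
    "citation": "Xia T. et al. (1998) Thermodynamic parameters for an expanded nearest-neighbor model for formation of RNA duplexes with Watson-Crick base pairs. Biochemistry 37:14719-14735.",
    "duplex_type": "RNA/RNA",
    "comment": "Watson-Crick stacks only; terminal-AU penalty omitted in this two-state summary. Keys are the top-strand dinucleotide 5'->3'.",
    "initiation": {"dH": 3.61, "dS": -1.5},
    "stacks": {
      "AA": {"dH": -6.82, "dS": -19.0},
      "AC": {"dH": -11.4, "dS": -29.5},
      "AG": {"dH": -10.48, "dS": -27.1},
      "AU": {"dH": -9.38, "dS": -26.7},
      "CA": {"dH": -10.44, "dS": -26.9},
      "CC": {"dH": -13.39, "dS": -32.7},
      "CG": {"dH": -10.64, "dS": -26.7},
      "CU": {"dH": -10.48, "dS": -27.1},
      "GA": {"dH": -12.44, "dS": -32.5},
      "GC": {"dH": -14.88, "dS": -36.9},
      "GG": {"dH": -13.39, "dS": -32.7},
      "GU": {"dH": -11.4, "dS": -29.5},
      "UA": {"dH": -7.69, "dS": -20.5},
      "UC": {"dH": -12.44, "dS": -32.5},
      "UG": {"dH": -10.44, "dS": -26.9},
      "UU": {"dH": -6.82, "dS": -19.0}
    }
  }
}
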