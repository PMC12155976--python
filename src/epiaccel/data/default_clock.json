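{
  "name": "blood-5cpg",
  "description": "Five-CpG pyrosequencing DNAm-age clock (ELOVL2, C1orf132/MIR29B2C, TRIM59, KLF14, FHL2); methylation in percentage points.",
  "intercept": "3.26847784751817",
  "sites": [
    {"key": "methC7-ELOVL2", "gene": "ELOVL2", "coefficient": "0.465445549010653"},
    {"key": "methC1-C1orf132", "gene": "C1orf132", "coefficient": "-0.355450171437202"},
    {"key": "methC7-TRIM59", "gene": "TRIM59", "coefficient": "0.306488541137007"},
    {"key": "methC1-KLF14", "gene": "KLF14", "coefficient": "0.832684435238792"},
    {"key": "methC2-FHL2", "gene": "FHL2", "coefficient": "0.237081243617191"}
  ]
}
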