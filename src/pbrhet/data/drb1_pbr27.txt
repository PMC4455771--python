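# Builtin PBR mask "drb1-27": 27 peptide-binding-region codons of HLA-DRB1,
# numbered 1-based on the mature beta-1 protein.
# Reconstructed list: the 24 DR beta-chain peptide-contact residues of the
# crystal-structure analysis of Brown et al. (1993) plus sites 57, 67 and 90,
# which later structural and peptide-binding assays identified as pocket
# residues and which this analysis includes as PBR.
9
11
13
26
28
30
32
37
38
47
56
57
60
61
65
67
68
70
71
74
78
81
82
85
86
89
90
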