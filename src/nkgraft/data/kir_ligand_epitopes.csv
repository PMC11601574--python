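allele,epitope
# KIR-ligand epitope assignments by HLA allele group (1-field rows) with
# 2-field exceptions.  Lookup is exact 2-field first, then 1-field fallback.
# Epitopes: bw4 (KIR3DL1 ligand), bw6 (no KIR ligand), c1 (KIR2DL2/L3),
# c2 (KIR2DL1), a3a11 (KIR3DL2), none.
# HLA-A: Bw4-motif allotypes counted toward Bw4 copy number are A*23, A*24,
# A*32; A*03 and A*11 carry the KIR3DL2 epitope.
A*01,none
A*02,none
A*03,a3a11
A*11,a3a11
A*23,bw4
A*24,bw4
A*25,none
A*26,none
A*29,none
A*30,none
A*31,none
A*32,bw4
A*33,none
A*34,none
A*36,none
A*66,none
A*68,none
A*69,none
A*74,none
A*80,none
# HLA-B: Bw4 vs Bw6 follows the serologic motif at residues 77-83.
B*07,bw6
B*08,bw6
B*13,bw4
B*14,bw6
B*15,bw6
B*15:13,bw4
B*15:16,bw4
B*15:17,bw4
B*15:23,bw4
B*15:24,bw4
B*18,bw6
B*27,bw4
B*27:08,bw6
B*35,bw6
B*37,bw4
B*38,bw4
B*39,bw6
B*40,bw6
B*41,bw6
B*42,bw6
B*44,bw4
B*45,bw6
B*46,bw6
B*46:01,c1
B*47,bw4
B*48,bw6
B*49,bw4
B*50,bw6
B*51,bw4
B*52,bw4
B*53,bw4
B*54,bw6
B*55,bw6
B*56,bw6
B*57,bw4
B*58,bw4
B*59,bw4
B*67,bw6
B*73,bw6
B*73:01,c1
B*78,bw6
B*81,bw6
B*82,bw6
# Common 2-field alleles listed explicitly (same epitope as their group).
A*01:01,none
A*02:01,none
A*03:01,a3a11
A*11:01,a3a11
A*23:01,bw4
A*24:02,bw4
A*25:01,none
A*26:01,none
A*29:02,none
A*30:01,none
A*31:01,none
A*32:01,bw4
A*33:01,none
A*66:01,none
A*68:01,none
B*07:02,bw6
B*08:01,bw6
B*13:02,bw4
B*14:02,bw6
B*15:01,bw6
B*18:01,bw6
B*27:05,bw4
B*35:01,bw6
B*37:01,bw4
B*38:01,bw4
B*39:01,bw6
B*40:01,bw6
B*44:02,bw4
B*44:03,bw4
B*45:01,bw6
B*49:01,bw4
B*50:01,bw6
B*51:01,bw4
B*52:01,bw4
B*53:01,bw4
B*55:01,bw6
B*57:01,bw4
B*58:01,bw4
B*59:01,bw4
# HLA-C: dimorphism at residue 80 partitions every allele into C1 (Asn80)
# or C2 (Lys80).
C*01,c1
C*02,c2
C*03,c1
C*04,c2
C*05,c2
C*06,c2
C*07,c1
C*08,c1
C*12,c1
C*14,c1
C*15,c2
C*16,c1
C*16:02,c2
C*17,c2
C*18,c2
C*01:02,c1
C*02:02,c2
C*03:03,c1
C*03:04,c1
C*04:01,c2
C*05:01,c2
C*06:02,c2
C*07:01,c1
C*07:02,c1
C*08:02,c1
C*12:03,c1
C*14:02,c1
C*15:02,c2
C*16:01,c1
C*17:01,c2
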