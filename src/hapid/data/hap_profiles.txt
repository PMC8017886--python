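# Pfam profiles accepted as evidence for high-abundance proteins:
# ribosomal proteins and translation elongation factors. Users may
# replace this file with their own curated list (one name per line).
Ribosomal_L1
Ribosomal_L2
Ribosomal_L2_C
Ribosomal_L3
Ribosomal_L4
Ribosomal_L5
Ribosomal_L5_C
Ribosomal_L6
Ribosomal_L9_C
Ribosomal_L9_N
Ribosomal_L10
Ribosomal_L11
Ribosomal_L11_N
Ribosomal_L12
Ribosomal_L13
Ribosomal_L14
Ribosomal_L16
Ribosomal_L17
Ribosomal_L18p
Ribosomal_L19
Ribosomal_L20
Ribosomal_L21p
Ribosomal_L22
Ribosomal_L23
Ribosomal_L24
Ribosomal_L25p
Ribosomal_L27
Ribosomal_L28
Ribosomal_L29
Ribosomal_L30
Ribosomal_L31
Ribosomal_L32p
Ribosomal_L33
Ribosomal_L34
Ribosomal_L35p
Ribosomal_L36
Ribosomal_S2
Ribosomal_S3_C
Ribosomal_S3Ae
Ribosomal_S4
Ribosomal_S5
Ribosomal_S5_C
Ribosomal_S6
Ribosomal_S7
Ribosomal_S8
Ribosomal_S9
Ribosomal_S10
Ribosomal_S11
Ribosomal_S12
Ribosomal_S13
Ribosomal_S14
Ribosomal_S15
Ribosomal_S16
Ribosomal_S17
Ribosomal_S18
Ribosomal_S19
Ribosomal_S20p
Ribosomal_S21
Ribosomal_S30AE
Ribosom_S12_S23
S4
KOW
L25p
GTP_EFTU
GTP_EFTU_D2
GTP_EFTU_D3
EFG_C
EFG_II
EFG_III
EFG_IV
EF_TS
EF-G_bact
EF1_GNE
Transl_elong_fac
EF1G
Elong-fact-P_C
Elong_Iga_bind
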