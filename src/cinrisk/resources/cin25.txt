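# CIN25 chromosomal-instability signature: the 25 genes most correlated with
# total functional aneuploidy across solid tumours (Carter et al. signature).
# Symbols modernised to current HGNC where the rename is unambiguous
# (CDC2->CDK1, CNAP1->NCAPD2, CDC45L->CDC45). Matching is case-insensitive.
TPX2
PRC1
FOXM1
CDK1
TGIF2
MCM2
H2AFZ
TOP2A
PCNA
UBE2C
MELK
TRIP13
NCAPD2
MCM7
RNASEH2A
RAD51AP1
KIF20A
CDC45
MAD2L1
ESPL1
CCNB2
FEN1
TTK
CCT5
RFC4
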