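# CIN70 chromosomal-instability signature: the 70 genes most correlated with
# total functional aneuploidy across solid tumours (Carter et al. signature);
# the first 25 entries are the CIN25 subset.
# Symbols modernised to current HGNC where the rename is unambiguous
# (CDC2->CDK1, CNAP1->NCAPD2, CDC45L->CDC45, ch-TOG->CKAP5, CTPS->CTPS1,
# BRRN1->NCAPH, TOPK->PBK, SFRS2->SRSF2, STK6->AURKA). Three legacy
# identifiers without a stable one-to-one modern mapping are kept verbatim
# (MTB, FLJ10036, KIAA0286). Matching is case-insensitive.
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
ATAD2
CKAP5
NUP205
CDC20
CKS2
RRM2
ELAVL1
CCNB1
RRM1
AURKB
MSH6
EZH2
CTPS1
DKC1
OIP5
CDCA8
PTTG1
CEP55
H2AFX
CMAS
NCAPH
MCM10
LSM4
MTB
ASF1B
ZWINT
PBK
FLJ10036
CDCA3
ECT2
CDC6
UNG
MTCH2
RAD21
ACTL6A
GPI
SRSF2
HDGF
NXT1
NEK2
DHCR7
AURKA
NDUFAB1
KIAA0286
KIF4A
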