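TP53
EGFR
KRAS
STK11
RBM10
KEAP1
ERBB2
SETD2
SMARCA4
NF1
BCORL1
FAT4
BRAF
MET
PIK3CA
CTNNB1
ARID1A
ARID1B
ARID2
ATM
BAP1
CDKN2A
CHEK2
CMTR2
COL11A1
CREBBP
CUL3
DOT1L
EP300
EPHA4
FANCM
FBXW7
FGFR4
GNAS
KDM5C
KMT2C
KMT2D
LRP1B
MAP2K1
MDM2
MGA
MYC
NCOA6
NKX2-1
NOTCH1
NRAS
NTRK3
PBRM1
PDGFRB
PIK3R1
POLE
PPP3CA
PTEN
PTPRD
RAF1
RB1
RBM5
RIT1
ROBO2
RNF43
SETBP1
SF3B1
SMAD4
SOX2
STAG2
TERT
TGFBR1
TGFBR2
TSC1
U2AF1
WRN
ZFHX3
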