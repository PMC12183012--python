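# Male-infertility diagnostic gene panel (130 genes), grouped by primary phenotype.
# Curated from published gene-disease validity assessments for male infertility.
# oligo-/azoospermia (52)
TEX11
TEX12
TEX14
TEX15
M1AP
NR5A1
DMRT1
SYCP2
SYCP3
KLHL10
MEIOB
STAG3
SYCE1
TDRD9
FANCM
XRCC2
MEI1
SPINK2
NANOS1
WT1
AR
ANOS1
CHD7
FGFR1
FGF8
GNRHR
GNRH1
KISS1R
KISS1
PROK2
PROKR2
TAC3
TACR3
MCM8
MCM9
MSH4
MSH5
DMC1
SHOC1
SPO11
MAJIN
TERB1
TERB2
STX2
RNF212
HSF2
SIX6OS1
PNLDC1
RBBP7
CCDC155
HROB
PIWIL1
# CBAVD (2)
CFTR
ADGRG2
# MMAF / PCD (34)
DNAH1
DNAH2
DNAH5
DNAH6
DNAH8
DNAH11
DNAH17
DNAI1
DNAI2
DNAL1
CFAP43
CFAP44
CFAP47
CFAP58
CFAP65
CFAP69
CFAP70
CFAP91
CFAP251
TTC12
TTC21A
TTC29
QRICH2
AK7
ARMC2
SPEF2
FSIP2
DZIP1
CCDC39
CCDC40
CCDC103
DRC1
LRRC6
ZMYND10
# acephalic spermatozoa (3)
SUN5
PMFBP1
TSGA10
# globozoospermia (2)
DPY19L2
SPATA16
# fertilization failure (2)
PLCZ1
ACTL7A
# astheno-/teratozoospermia, other (7)
AURKC
CATSPER1
CATSPER2
SEPTIN12
SLC26A8
GALNTL5
SPACA1
# AZF-region genes (28)
USP9Y
DDX3Y
UTY
TMSB4Y
KDM5D
EIF1AY
RPS4Y2
NLGN4Y
VCY
VCY1B
XKRY
HSFY1
HSFY2
PRY
PRY2
RBMY1A1
RBMY1B
RBMY1D
RBMY1E
RBMY1F
RBMY1J
BPY2
BPY2B
BPY2C
DAZ1
DAZ2
DAZ3
DAZ4
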