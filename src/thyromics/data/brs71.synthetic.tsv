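# BRAF(V600E)-RAS score signature (71 genes, labelled).
# Curated synthetic stand-in; negative BRS = BRAF-like. Edit freely.
gene	class
FN1	BRAF-like
MET	BRAF-like
TIMP1	BRAF-like
SERPINA1	BRAF-like
SLPI	BRAF-like
QPCT	BRAF-like
CITED1	BRAF-like
PROS1	BRAF-like
CLDN1	BRAF-like
LAMB3	BRAF-like
TACSTD2	BRAF-like
GALE	BRAF-like
SDC4	BRAF-like
PLOD2	BRAF-like
PRSS23	BRAF-like
CHI3L1	BRAF-like
KRT19	BRAF-like
LGALS3	BRAF-like
CDH3	BRAF-like
MUC1	BRAF-like
S100A4	BRAF-like
ANXA1	BRAF-like
TNC	BRAF-like
COL1A1	BRAF-like
ITGA3	BRAF-like
RUNX1	BRAF-like
ANGPTL4	BRAF-like
EMP2	BRAF-like
SCEL	BRAF-like
TGFBI	BRAF-like
CTSH	BRAF-like
GJB3	BRAF-like
KRT7	BRAF-like
NGEF	BRAF-like
DUSP9	BRAF-like
ETV6	BRAF-like
TFF3	RAS-like
SLC26A7	RAS-like
MT1G	RAS-like
CRABP1	RAS-like
FHL1	RAS-like
ITPR1	RAS-like
GPM6A	RAS-like
CDH16	RAS-like
PKHD1L1	RAS-like
FRMD3	RAS-like
EPHB1	RAS-like
SORBS2	RAS-like
PPARGC1A	RAS-like
BMP8A	RAS-like
SLC4A4	RAS-like
HGD	RAS-like
TPPP3	RAS-like
ABI3BP	RAS-like
MYH10	RAS-like
LMO3	RAS-like
DPP6	RAS-like
SCNN1G	RAS-like
KCNJ2	RAS-like
PLCB1	RAS-like
RGS4	RAS-like
SYT1	RAS-like
NTRK2	RAS-like
MATN2	RAS-like
GABRB2	RAS-like
ANK2	RAS-like
PDE8B	RAS-like
COL23A1	RAS-like
SEMA3D	RAS-like
TTYH1	RAS-like
NRCAM	RAS-like
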