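# ERK score signature (52 genes).
# Curated synthetic stand-in: MAPK transcriptional-output genes; edit freely.
gene
SPRY1
SPRY2
SPRY4
DUSP4
DUSP5
DUSP6
ETV1
ETV4
ETV5
PHLDA1
EPHA2
EPHA4
FOSL1
MYC
CCND1
ELK3
EGR1
ETS2
FOS
JUN
JUNB
MAP2K3
TRIB2
SHC1
IER3
SLC16A1
GJA1
LIF
PLAUR
PLAU
SERPINE1
VEGFA
HBEGF
EREG
AREG
TGFA
SPRED1
SPRED2
RASGRP1
PEA15
CDC25A
E2F1
MCM7
PCNA
RRM2
KIF2C
BUB1
CCNB1
AURKA
PLK1
CENPA
MKI67
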