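# Thyroid differentiation score signature (16 genes).
# Curated synthetic stand-in: thyroid function/metabolism markers; edit freely.
gene
DIO1
DIO2
DUOX1
DUOX2
FOXE1
GLIS3
NKX2-1
PAX8
SLC26A4
SLC5A5
SLC5A8
TG
THRA
TPO
TSHR
TFF3
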