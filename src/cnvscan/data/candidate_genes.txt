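# ASD known/candidate risk genes flanking the reported intergenic loci
NRXN1
ARPP21
C3orf58
ZIC1
ZIC4
EPHA5
MOCS1
SEMA3C
UNC5D
NRG1
ZHX2
ASTN2
OLFM1
RXRA
LUZP2
LRRC4C
MRGPRD
CDH8
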