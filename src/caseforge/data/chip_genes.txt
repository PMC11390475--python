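ASXL1
BRAF
CALR
DNMT3A
GNB1
IDH2
JAK2
KRAS
MPL
NRAS
PPM1D
PRPF8
SF3B1
SRSF2
TET2
TP53
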