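# synthetic stand-in panel: sizes match the study's curated list; symbols beyond the seeded real ones are synthetic
MYO6
HOMER2
WFS1
MYH9
COL11A2
TECTA
TJP2
GJB2
GPR98
PAX2
LRIG3
LAMA2
CDH23
DMD
DUOX2
RBPJ
USH2A
COL11A1
NAV2
CPXM2
COL4A4
LRP2
MYO15A
TSPEAR
PCDH15
OTOG
MECOM
NTN1
TCOF1
CELSR1
SLC9A3R1
COL9A1
ALMS1
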