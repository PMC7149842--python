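# Candidate gene panel: genes implicated in vertebral segmentation defects (n=96)
ACVR2B
ALDH1A2
ANKRD11
AXIN2
BAZ1B
BMP4
BMP7
CDX1
CDX2
CDX4
CER1
CHD7
CHRD
COG1
CTNNB1
CYP26A1
CYP26B1
DKK1
DLL1
DLL3
DLL4
DMRT2
DUSP6
EFNB2
EPHA4
FGF4
FGF8
FGFR1
FOXC1
FOXC2
FRAS1
FREM2
FUZ
GDF11
GDF3
GDF6
GLI1
GLI2
GLI3
GRIP1
HES1
HES7
HHAT
HOXA10
HOXA2
HOXB4
HOXB6
HOXC8
HOXD10
HOXD13
JAG1
JAG2
KMT2D
LFNG
LRP6
MAP3K7
MEOX1
MEOX2
MESP1
MESP2
MIB1
MYF5
MYO18B
NKD1
NOG
NOTCH1
NOTCH2
NRARP
PAX1
PAX3
PAX9
PBX1
POFUT1
POR
PSEN1
PTCH1
RARB
RBPJ
RIPPLY1
RIPPLY2
SHH
SLC35A3
SMO
SOX9
SUFU
TBX1
TBX15
TBX18
TBX6
TBXT
TCF15
UNCX
VANGL1
WNT3A
WNT5A
WNT7A
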