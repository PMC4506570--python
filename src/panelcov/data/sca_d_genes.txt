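ABCC9
ACTA2
ACTC1
ACTN2
AKAP9
ANK2
ANKRD1
BAG3
BRAF
CACNA1B
CACNA1C
CACNA2D1
CACNB2
CALR3
CASQ2
CAV3
CBS
COL3A1
COL5A1
COL5A2
CRYAB
CSRP3
CTF1
DES
DMD
DPP6
DSC2
DSG2
DSP
DTNA
ELN
EMD
EYA4
FBN1
FBN2
FHL2
FKTN
GATAD1
GLA
GPD1L
HRAS
JPH2
JUP
KCNE1
KCNE2
KCNE3
KCNH2
KCNJ2
KCNJ5
KCNJ8
KCNQ1
KRAS
LAMA4
LAMP2
LDB3
LMNA
MAP2K1
MYBPC3
MYH6
MYH7
MYH11
MYL2
MYL3
MYLK2
MYOZ2
NEXN
NRAS
PKP2
PLN
PRKAG2
PSEN1
PSEN2
PTPN11
RAF1
RBM20
RPSA
RYR2
SCN1B
SCN3B
SCN4B
SCN5A
SDHA
SGCD
SHOC2
SLC25A4
SLC2A10
SMAD3
SNTA1
SOS1
TAZ
TCAP
TGFB3
TGFBR1
TGFBR2
TMEM43
TMPO
TNNC1
TNNI3
TNNT2
TPM1
TTN
TTR
VCL
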