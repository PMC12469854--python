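IGFN1
PTCHD4
PKP1
NRAP
CMA1
MIR675
AQP7B
ADCYAP1R1
ANGPTL7
MYOZ1
HOTS
LOC112267876
JPH2
LOC102724852
PLN
H19
LINC01436
MUC3A
MYH1
LMO3
PLCXD3
HIF3A
ADAMTS15
SRL
CASQ2
HOXD9
REM1
HSPB6
MEOX1
NTM
SLC52A3
CCL21
PTN
CYP26B1
INSRR
IGHV7-4-1
ADAMTSL1
COX4I2
LAMA3
GPR15
SERPINA3
FLNC
PERM1
TLL1
TREM2
STXBP6
NES
CCDC85A
LOC105375249
RERGL
CLIC5
SH3RF2
SYPL2
CCL19
RASD2
TCF15
CACNA1H
SLCO2A1
ALDH1A2
SSTR1
C1QTNF7
GPR17
KRT222
POSTN
FAM107A
PLPPR4
L1CAM
ANKRD29
TRIM63
IRX6
STC1
LOC105377979
MET
SHISAL1
TCEAL2
EBF2
ADAMTS12
SLIT3
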