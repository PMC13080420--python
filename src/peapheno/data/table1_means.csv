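trait,control_mean,drought_mean
DB,278.17,188.49
CH,2081.44,1367.50
SOL,0.15,0.16
NPCI,0.18,0.14
GLI,0.29,0.27
NDVI,0.21,0.20
PSRI,0.19,0.16
TA,104.58,98.71
SA,173980.09,117979.18
PhE,0.77,0.78
WUE,2214.52,1691.62
FW,23.29,12.32
DW,4.11,2.41
PH,123.26,91.44
TLA,818.14,466.32
SLA,243.53,219.53
LWR,0.30,0.32
LAR,200.30,197.73
RWC,75.41,63.348
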