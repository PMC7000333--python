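gene
CDK1
PRKCB
PRKCZ
PPARD
STAT3
THRA
CCL2
CCR2
SLC1A1
PTGER3
AKR1B10
LGALS3
BIRC2
HSD17B2
P2RX7
PLD2
CYP2J2
MGLL
FKBP4
PTGES
ALOX5AP
P2RY6
AKR1A1
MAPT
CYP51A1
TRAP1
AKR1C1
AKR1C3
AKR1C2
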