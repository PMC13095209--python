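node	categories
AVA	locomotion;mechanosensation
AVB	locomotion
AVD	locomotion;mechanosensation
AVE	locomotion
PVC	locomotion;mechanosensation
ALA	mechanosensation
ALM	mechanosensation
AVM	mechanosensation
PLM	mechanosensation
PVM	mechanosensation
FLP	mechanosensation
ASH	mechanosensation;chemotaxis
ASEL	chemotaxis
ASER	chemotaxis
AWA	chemotaxis
AWB	chemotaxis
AWCL	chemotaxis
AWCR	chemotaxis
AIY	chemotaxis
AIZ	chemotaxis
RIA	chemotaxis;locomotion
RIB	locomotion
RIM	locomotion
RMD_DV	locomotion
SMD	locomotion
DA	locomotion
DB	locomotion
VA	locomotion
VB	locomotion
DD	locomotion
VD	locomotion
ASI	chemotaxis;feeding
ASJ	chemotaxis
ASK	chemotaxis
ADF	chemotaxis;feeding
NSM	feeding
M3	feeding
M5	feeding
I5	feeding
MC	feeding
PQR	oxygen_sensation
AQR	oxygen_sensation
URX	oxygen_sensation
RIC	locomotion;mate_searching
DVC	locomotion;mechanosensation
AIM	mate_searching
AIB	locomotion
PHA	chemotaxis
PHB	chemotaxis
PHC	mechanosensation;mating
HOA	mating
HOB	mating
PCA	mating
PCB	mating
PCC	mating
SPC	mating
SPD	mating
SPV	mating
PVV	mating
PVY	mating
PVX	mating
EF1	mating
EF2	mating
EF3	mating
CA01	mating
CP01	mating
R1A	mating
R2A	mating
R3A	mating
R4A	mating
R5A	mating
R6A	mating
R7A	mating
R8A	mating
R9A	mating
MCM	mate_searching;learning
CEM	mate_searching
HSN	egg_laying
VC	egg_laying
uv1	egg_laying
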