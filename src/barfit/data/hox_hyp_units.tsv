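unit_id	promoter	position	gene
MBH	P_MBH	1	hoxK
MBH	P_MBH	2	hoxG
MBH	P_MBH	3	hoxZ
MBH	P_MBH	4	hoxM
MBH	P_MBH	5	hoxL
MBH	P_MBH	6	hoxO
MBH	P_MBH	7	hoxQ
MBH	P_MBH	8	hoxR
MBH	P_MBH	9	hoxT
MBH	P_MBH	10	hoxV
HYP	P_hyp	1	hypA1
HYP	P_hyp	2	hypB1
HYP	P_hyp	3	hypF
HYP	P_hyp	4	hypC
HYP	P_hyp	5	hypD
HYP	P_hyp	6	hypE
HYP	P_hyp	7	hypX
REG	P_reg	1	hoxA
REG	P_reg	2	hoxB
REG	P_reg	3	hoxC
REG	P_reg	4	hoxJ
SH	P_SH	1	hoxF
SH	P_SH	2	hoxU
SH	P_SH	3	hoxY
SH	P_SH	4	hoxH
SH	P_SH	5	hoxW
SH	P_SH	6	hoxI
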