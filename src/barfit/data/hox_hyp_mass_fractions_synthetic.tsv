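gene	psi_percent
hoxK	0.020
hoxG	0.050
hoxZ	0.020
hoxM	0.010
hoxL	0.020
hoxO	0.010
hoxQ	0.010
hoxR	0.010
hoxT	0.010
hoxV	0.020
hypA1	0.030
hypB1	0.060
hypF	0.100
hypC	0.040
hypD	0.120
hypE	0.080
hypX	0.090
hoxA	0.050
hoxB	0.100
hoxC	0.080
hoxJ	0.040
hoxF	0.400
hoxU	0.250
hoxY	0.200
hoxH	0.450
hoxW	0.050
hoxI	0.100
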