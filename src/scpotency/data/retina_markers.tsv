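cell_type	gene	direction
Rods	RHO	positive
Rods	NR2E3	positive
Rods	GNAT1	positive
Rods	PDE6B	positive
Cones	ARR3	positive
Cones	OPN1SW	positive
Cones	PDE6H	positive
Cones	GNAT2	positive
MullerGlia	RLBP1	positive
MullerGlia	GLUL	positive
MullerGlia	SLC1A3	positive
Bipolar	VSX2	positive
Bipolar	GRIK1	positive
Bipolar	CABP5	positive
Horizontal	ONECUT1	positive
Horizontal	ONECUT2	positive
Horizontal	LHX1	positive
Amacrine	GAD1	positive
Amacrine	SLC6A9	positive
Amacrine	TFAP2A	positive
Progenitors	SFRP2	positive
Progenitors	SOX2	positive
Progenitors	MKI67	positive
Other	COL1A1	positive
Other	BEST1	positive
Other	TTR	positive
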