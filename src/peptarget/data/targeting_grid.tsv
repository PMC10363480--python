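# Construct-targeting outcome grid, transcribed from the source study's
# reported per-construct fluorescence calls. Rows A-L encode the construct
# grammar (K/R variant x optional cTP-N x optional C-element), columns a-m
# the 13 antimicrobial core peptides, columns n-s controls (random peptides,
# TP helix fragments, no-core and poly-alanine constructs).
# Calls: NONE / PARTIAL / FULL per organelle.
# note codes: text = explicitly enumerated in the running text;
# implied = required by the text-level change/tally enumeration;
# default = no targeting reported anywhere, called NONE;
# lowconf = wording ambiguous, call chosen conservatively.
row	column	code	mito	chloro	note
A	a	B2I_K	FULL	NONE	text
A	b	MII_K	PARTIAL	NONE	text
A	c	R2G_K	NONE	NONE	default
A	d	DS4_K	NONE	NONE	default
A	e	DDM_K	NONE	NONE	default
A	f	B1E_K	NONE	NONE	default
A	g	CP3_K	NONE	NONE	default
A	h	S1D_K	NONE	NONE	default
A	i	E1S_K	NONE	NONE	default
A	j	LCA_K	NONE	NONE	default
A	k	SIM_K	NONE	NONE	default
A	l	B15_K	NONE	NONE	default
A	m	EHF_K	NONE	NONE	default
B	a	B2I_R	FULL	NONE	implied
B	b	MII_R	FULL	NONE	text
B	c	R2G_R	PARTIAL	NONE	text
B	d	DS4_R	NONE	NONE	default
B	e	DDM_R	NONE	NONE	default
B	f	B1E_R	NONE	NONE	default
B	g	CP3_R	PARTIAL	NONE	text
B	h	S1D_R	NONE	NONE	default
B	i	E1S_R	NONE	NONE	default
B	j	LCA_R	NONE	NONE	default
B	k	SIM_R	NONE	NONE	default
B	l	B15_R	NONE	NONE	default
B	m	EHF_R	NONE	NONE	default
C	a	B2I_K^m	FULL	NONE	text
C	b	MII_K^m	PARTIAL	NONE	text
C	c	R2G_K^m	PARTIAL	NONE	text
C	d	DS4_K^m	NONE	NONE	default
C	e	DDM_K^m	NONE	NONE	default
C	f	B1E_K^m	NONE	NONE	default
C	g	CP3_K^m	NONE	NONE	default
C	h	S1D_K^m	NONE	NONE	default
C	i	E1S_K^m	NONE	NONE	default
C	j	LCA_K^m	NONE	NONE	default
C	k	SIM_K^m	NONE	NONE	default
C	l	B15_K^m	NONE	NONE	default
C	m	EHF_K^m	NONE	NONE	default
D	a	B2I_R^m	FULL	NONE	implied
D	b	MII_R^m	PARTIAL	NONE	implied
D	c	R2G_R^m	FULL	NONE	text
D	d	DS4_R^m	NONE	NONE	default
D	e	DDM_R^m	NONE	NONE	default
D	f	B1E_R^m	NONE	NONE	default
D	g	CP3_R^m	PARTIAL	NONE	text
D	h	S1D_R^m	NONE	NONE	default
D	i	E1S_R^m	PARTIAL	NONE	text
D	j	LCA_R^m	NONE	NONE	default
D	k	SIM_R^m	NONE	NONE	default
D	l	B15_R^m	NONE	NONE	default
D	m	EHF_R^m	NONE	PARTIAL	text
E	a	B2I_K^c	FULL	NONE	text
E	b	MII_K^c	PARTIAL	NONE	text
E	c	R2G_K^c	NONE	NONE	default
E	d	DS4_K^c	NONE	NONE	default
E	e	DDM_K^c	NONE	NONE	default
E	f	B1E_K^c	NONE	NONE	default
E	g	CP3_K^c	NONE	NONE	default
E	h	S1D_K^c	NONE	FULL	implied
E	i	E1S_K^c	NONE	NONE	default
E	j	LCA_K^c	NONE	PARTIAL	text
E	k	SIM_K^c	NONE	NONE	default
E	l	B15_K^c	NONE	PARTIAL	implied
E	m	EHF_K^c	NONE	PARTIAL	implied
F	a	B2I_R^c	FULL	NONE	implied
F	b	MII_R^c	PARTIAL	NONE	implied
F	c	R2G_R^c	NONE	NONE	default
F	d	DS4_R^c	NONE	NONE	default
F	e	DDM_R^c	NONE	NONE	default
F	f	B1E_R^c	NONE	NONE	default
F	g	CP3_R^c	NONE	PARTIAL	text
F	h	S1D_R^c	NONE	PARTIAL	implied
F	i	E1S_R^c	NONE	NONE	default
F	j	LCA_R^c	NONE	PARTIAL	implied
F	k	SIM_R^c	NONE	NONE	default
F	l	B15_R^c	NONE	PARTIAL	implied
F	m	EHF_R^c	NONE	FULL	text
G	a	^cB2I_K	PARTIAL	NONE	implied
G	b	^cMII_K	PARTIAL	NONE	implied
G	c	^cR2G_K	PARTIAL	NONE	implied
G	d	^cDS4_K	NONE	NONE	default
G	e	^cDDM_K	PARTIAL	NONE	implied
G	f	^cB1E_K	NONE	NONE	implied
G	g	^cCP3_K	NONE	NONE	default
G	h	^cS1D_K	PARTIAL	NONE	text
G	i	^cE1S_K	NONE	NONE	default
G	j	^cLCA_K	NONE	NONE	default
G	k	^cSIM_K	NONE	PARTIAL	text
G	l	^cB15_K	NONE	NONE	default
G	m	^cEHF_K	NONE	NONE	default
H	a	^cB2I_R	PARTIAL	NONE	text
H	b	^cMII_R	PARTIAL	NONE	implied
H	c	^cR2G_R	FULL	NONE	implied
H	d	^cDS4_R	NONE	NONE	default
H	e	^cDDM_R	PARTIAL	NONE	text
H	f	^cB1E_R	PARTIAL	NONE	text
H	g	^cCP3_R	NONE	PARTIAL	text
H	h	^cS1D_R	PARTIAL	NONE	implied
H	i	^cE1S_R	NONE	PARTIAL	text
H	j	^cLCA_R	NONE	NONE	default
H	k	^cSIM_R	NONE	FULL	implied
H	l	^cB15_R	NONE	PARTIAL	text
H	m	^cEHF_R	NONE	PARTIAL	text
I	a	^cB2I_K^m	PARTIAL	NONE	implied
I	b	^cMII_K^m	PARTIAL	NONE	implied
I	c	^cR2G_K^m	NONE	NONE	default
I	d	^cDS4_K^m	NONE	NONE	default
I	e	^cDDM_K^m	NONE	NONE	default
I	f	^cB1E_K^m	PARTIAL	PARTIAL	text
I	g	^cCP3_K^m	NONE	PARTIAL	text
I	h	^cS1D_K^m	PARTIAL	PARTIAL	text
I	i	^cE1S_K^m	NONE	PARTIAL	text
I	j	^cLCA_K^m	NONE	PARTIAL	text
I	k	^cSIM_K^m	NONE	PARTIAL	text
I	l	^cB15_K^m	NONE	PARTIAL	text
I	m	^cEHF_K^m	NONE	PARTIAL	text
J	a	^cB2I_R^m	PARTIAL	PARTIAL	text
J	b	^cMII_R^m	PARTIAL	PARTIAL	text
J	c	^cR2G_R^m	NONE	NONE	default
J	d	^cDS4_R^m	NONE	NONE	default
J	e	^cDDM_R^m	NONE	NONE	default
J	f	^cB1E_R^m	PARTIAL	PARTIAL	text
J	g	^cCP3_R^m	NONE	NONE	text
J	h	^cS1D_R^m	PARTIAL	PARTIAL	text
J	i	^cE1S_R^m	NONE	PARTIAL	text
J	j	^cLCA_R^m	NONE	NONE	text
J	k	^cSIM_R^m	NONE	PARTIAL	text
J	l	^cB15_R^m	NONE	PARTIAL	text
J	m	^cEHF_R^m	NONE	PARTIAL	text
K	a	^cB2I_K^c	NONE	PARTIAL	text
K	b	^cMII_K^c	NONE	PARTIAL	implied
K	c	^cR2G_K^c	PARTIAL	NONE	text
K	d	^cDS4_K^c	NONE	NONE	text
K	e	^cDDM_K^c	NONE	PARTIAL	implied
K	f	^cB1E_K^c	NONE	PARTIAL	implied
K	g	^cCP3_K^c	NONE	NONE	text
K	h	^cS1D_K^c	NONE	PARTIAL	implied
K	i	^cE1S_K^c	NONE	PARTIAL	implied
K	j	^cLCA_K^c	NONE	PARTIAL	implied
K	k	^cSIM_K^c	NONE	PARTIAL	implied
K	l	^cB15_K^c	NONE	PARTIAL	implied
K	m	^cEHF_K^c	NONE	PARTIAL	implied
L	a	^cB2I_R^c	NONE	FULL	text
L	b	^cMII_R^c	NONE	PARTIAL	implied
L	c	^cR2G_R^c	PARTIAL	PARTIAL	text
L	d	^cDS4_R^c	NONE	NONE	text
L	e	^cDDM_R^c	NONE	PARTIAL	implied
L	f	^cB1E_R^c	NONE	FULL	implied
L	g	^cCP3_R^c	NONE	PARTIAL	text
L	h	^cS1D_R^c	NONE	PARTIAL	implied
L	i	^cE1S_R^c	NONE	PARTIAL	implied
L	j	^cLCA_R^c	NONE	FULL	implied
L	k	^cSIM_R^c	NONE	PARTIAL	implied
L	l	^cB15_R^c	NONE	PARTIAL	implied
L	m	^cEHF_R^c	NONE	PARTIAL	implied
B	q	MH_R	PARTIAL	NONE	text
C	q	MH_K^m	NONE	NONE	lowconf
D	q	MH_R^m	PARTIAL	NONE	text
F	q	MH_R^c	NONE	PARTIAL	text
J	q	^cMH_R^m	NONE	NONE	text
L	q	^cMH_R^c	NONE	PARTIAL	text
H	p	^cCH_R	NONE	NONE	text
J	p	^cCH_R^m	NONE	NONE	text
K	p	^cCH_K^c	NONE	PARTIAL	lowconf
L	p	^cCH_R^c	NONE	FULL	text
K	n	^cRP1^c	NONE	NONE	text
K	o	^cRP2^c	NONE	NONE	text
K	r	^c-^c	NONE	PARTIAL	text
K	s	^cAA^c	NONE	PARTIAL	text
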