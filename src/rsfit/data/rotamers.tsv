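# Compact side-chain rotamer library: common rotamers per residue type with
# chi angles (degrees) and prior probabilities, a reduced set in the spirit
# of the penultimate rotamer compilations.  Columns are tab separated:
# res_type	name	prob	chi1	chi2	chi3	chi4
SER	p	0.48	62
SER	m	0.29	-65
SER	t	0.22	-177
CYS	m	0.50	-65
CYS	t	0.26	-177
CYS	p	0.23	62
THR	p	0.49	62
THR	m	0.43	-65
THR	t	0.07	-175
VAL	t	0.73	175
VAL	m	0.20	-60
VAL	p	0.06	63
ILE	mt	0.60	-65	170
ILE	mm	0.15	-57	-60
ILE	pt	0.13	62	170
ILE	tt	0.08	-177	166
LEU	mt	0.59	-65	175
LEU	tp	0.29	-177	65
LEU	mp	0.03	-85	65
ASP	m-20	0.51	-70	-15
ASP	t0	0.23	-175	0
ASP	p-10	0.14	62	-10
ASN	m-40	0.33	-65	-40
ASN	t-20	0.26	-174	-20
ASN	m110	0.12	-65	110
ASN	p-10	0.09	62	-10
GLU	mt-10	0.35	-67	180	-10
GLU	tt0	0.24	-177	177	0
GLU	mm-40	0.12	-65	-75	-40
GLU	pt-20	0.08	62	180	-20
GLN	mt-30	0.38	-67	180	-25
GLN	tt0	0.16	-177	177	0
GLN	mm-40	0.14	-66	-60	-40
MET	mmm	0.19	-65	-65	-70
MET	mtp	0.18	-67	177	72
MET	mtm	0.11	-67	177	-75
MET	ttp	0.11	-177	177	72
LYS	mttt	0.20	-67	180	180	180
LYS	tttt	0.16	-177	180	180	180
LYS	mtpt	0.08	-67	180	68	180
LYS	mmtt	0.07	-67	-68	180	180
ARG	mtt180	0.09	-67	180	180	180
ARG	mtt-85	0.08	-67	180	180	-85
ARG	ttt180	0.07	-177	180	180	180
ARG	mtm-85	0.06	-67	180	-65	-85
HIS	m-70	0.33	-65	-70
HIS	t-165	0.20	-177	-165
HIS	m170	0.13	-65	165
PHE	m-85	0.44	-65	-85
PHE	t80	0.33	-177	80
PHE	p90	0.13	62	90
TYR	m-85	0.43	-65	-85
TYR	t80	0.34	-177	80
TYR	p90	0.13	62	90
TRP	m95	0.32	-65	95
TRP	t-105	0.16	-177	-105
TRP	m-90	0.15	-65	-90
TRP	p-90	0.11	62	-90
PRO	down	1.00	-25	35
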