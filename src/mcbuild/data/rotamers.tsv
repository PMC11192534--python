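# Compact idealized rotamer library: modal chi values (degrees) per residue.
# Penultimate-style names; blank chi columns mean the residue has fewer chis.
# residue	name	chi1	chi2	chi3	chi4
SER	p	62
SER	t	-177
SER	m	-65
CYS	p	62
CYS	t	-177
CYS	m	-65
THR	p	62
THR	t	-175
THR	m	-65
VAL	p	63
VAL	t	175
VAL	m	-60
LEU	pp	62	80
LEU	tp	-177	65
LEU	tt	-172	147
LEU	mt	-65	175
LEU	mm	-85	65
ILE	pt	62	170
ILE	tt	-177	166
ILE	mt	-65	170
ILE	mm	-57	-60
MET	ptp	62	180	75
MET	ttp	-177	180	75
MET	ttm	-177	180	-75
MET	ttt	-177	180	180
MET	mtp	-65	180	75
MET	mtm	-65	180	-75
MET	mtt	-65	180	180
MET	mmm	-65	-65	-70
PHE	p90	62	90
PHE	t80	-177	80
PHE	m-85	-65	-85
PHE	m-30	-65	-30
TYR	p90	62	90
TYR	t80	-177	80
TYR	m-85	-65	-85
TYR	m-30	-65	-30
TRP	p-90	62	-90
TRP	p90	62	90
TRP	t-105	-177	-105
TRP	t90	-177	88
TRP	m95	-65	95
TRP	m-5	-65	-5
HIS	p-80	62	-75
HIS	t-160	-177	-165
HIS	t60	-177	60
HIS	m-70	-65	-70
HIS	m170	-65	165
ASP	p-10	62	-10
ASP	t30	-177	30
ASP	m-20	-70	-15
ASN	p-10	62	-10
ASN	t-20	-174	-20
ASN	t30	-177	30
ASN	m-20	-65	-20
ASN	m-80	-65	-75
GLU	pt-20	62	180	-20
GLU	tt0	-177	177	0
GLU	tp10	-177	65	10
GLU	mt-10	-67	180	-10
GLU	mm-40	-65	-65	-40
GLN	pt20	62	180	20
GLN	tt0	-177	177	0
GLN	mt-30	-67	180	-25
GLN	mm-40	-65	-65	-40
LYS	pttt	62	180	180	180
LYS	tttt	-177	180	180	180
LYS	mttt	-65	180	180	180
LYS	mttp	-65	180	180	65
LYS	mttm	-65	180	180	-65
LYS	mmtt	-65	-68	180	180
ARG	ptt180	62	180	180	180
ARG	ttt180	-177	180	180	180
ARG	mtt180	-67	180	180	180
ARG	mtt85	-67	180	180	85
ARG	mtt-85	-67	180	180	-85
PRO	endo	24
PRO	exo	-24
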