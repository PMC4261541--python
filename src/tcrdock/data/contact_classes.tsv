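# 18-class ACE/IFACE-style heavy-atom contact typing for the 20 amino acids.
# Class grouping reconstructed by chemical congruence (backbone N/CA/C/O, Gly CA,
# CB, aliphatic C, aromatic C, hydroxyl-bearing aromatic C, charged-adjacent C,
# amide N/O, carboxylate O, guanidinium/ring N, amine N, hydroxyl O, S).
residue	atom	contact_class
ALA	N	N
ALA	CA	CA
ALA	C	C
ALA	O	O
ALA	OXT	DOD
ALA	CB	CB
ARG	N	N
ARG	CA	CA
ARG	C	C
ARG	O	O
ARG	OXT	DOD
ARG	CB	CB
ARG	CG	LCD
ARG	CD	KCD
ARG	NE	RNE
ARG	CZ	YCZ
ARG	NH1	RNH
ARG	NH2	RNH
ASN	N	N
ASN	CA	CA
ASN	C	C
ASN	O	O
ASN	OXT	DOD
ASN	CB	CB
ASN	CG	C
ASN	OD1	O
ASN	ND2	NND
ASP	N	N
ASP	CA	CA
ASP	C	C
ASP	O	O
ASP	OXT	DOD
ASP	CB	CB
ASP	CG	C
ASP	OD1	DOD
ASP	OD2	DOD
CYS	N	N
CYS	CA	CA
CYS	C	C
CYS	O	O
CYS	OXT	DOD
CYS	CB	CB
CYS	SG	CSG
GLN	N	N
GLN	CA	CA
GLN	C	C
GLN	O	O
GLN	OXT	DOD
GLN	CB	CB
GLN	CG	LCD
GLN	CD	C
GLN	OE1	O
GLN	NE2	NND
GLU	N	N
GLU	CA	CA
GLU	C	C
GLU	O	O
GLU	OXT	DOD
GLU	CB	CB
GLU	CG	LCD
GLU	CD	C
GLU	OE1	DOD
GLU	OE2	DOD
GLY	N	N
GLY	CA	GC
GLY	C	C
GLY	O	O
GLY	OXT	DOD
HIS	N	N
HIS	CA	CA
HIS	C	C
HIS	O	O
HIS	OXT	DOD
HIS	CB	CB
HIS	CG	FCZ
HIS	ND1	HNE
HIS	CD2	FCZ
HIS	CE1	FCZ
HIS	NE2	HNE
ILE	N	N
ILE	CA	CA
ILE	C	C
ILE	O	O
ILE	OXT	DOD
ILE	CB	CB
ILE	CG1	LCD
ILE	CG2	LCD
ILE	CD1	LCD
LEU	N	N
LEU	CA	CA
LEU	C	C
LEU	O	O
LEU	OXT	DOD
LEU	CB	CB
LEU	CG	LCD
LEU	CD1	LCD
LEU	CD2	LCD
LYS	N	N
LYS	CA	CA
LYS	C	C
LYS	O	O
LYS	OXT	DOD
LYS	CB	CB
LYS	CG	LCD
LYS	CD	KCD
LYS	CE	KCD
LYS	NZ	KNZ
MET	N	N
MET	CA	CA
MET	C	C
MET	O	O
MET	OXT	DOD
MET	CB	CB
MET	CG	LCD
MET	SD	CSG
MET	CE	LCD
PHE	N	N
PHE	CA	CA
PHE	C	C
PHE	O	O
PHE	OXT	DOD
PHE	CB	CB
PHE	CG	FCZ
PHE	CD1	FCZ
PHE	CD2	FCZ
PHE	CE1	FCZ
PHE	CE2	FCZ
PHE	CZ	FCZ
PRO	N	N
PRO	CA	CA
PRO	C	C
PRO	O	O
PRO	OXT	DOD
PRO	CB	CB
PRO	CG	LCD
PRO	CD	KCD
SER	N	N
SER	CA	CA
SER	C	C
SER	O	O
SER	OXT	DOD
SER	CB	CB
SER	OG	SOG
THR	N	N
THR	CA	CA
THR	C	C
THR	O	O
THR	OXT	DOD
THR	CB	CB
THR	OG1	SOG
THR	CG2	LCD
TRP	N	N
TRP	CA	CA
TRP	C	C
TRP	O	O
TRP	OXT	DOD
TRP	CB	CB
TRP	CG	FCZ
TRP	CD1	FCZ
TRP	CD2	FCZ
TRP	NE1	RNE
TRP	CE2	FCZ
TRP	CE3	FCZ
TRP	CZ2	FCZ
TRP	CZ3	FCZ
TRP	CH2	FCZ
TYR	N	N
TYR	CA	CA
TYR	C	C
TYR	O	O
TYR	OXT	DOD
TYR	CB	CB
TYR	CG	FCZ
TYR	CD1	FCZ
TYR	CD2	FCZ
TYR	CE1	FCZ
TYR	CE2	FCZ
TYR	CZ	YCZ
TYR	OH	SOG
VAL	N	N
VAL	CA	CA
VAL	C	C
VAL	O	O
VAL	OXT	DOD
VAL	CB	CB
VAL	CG1	LCD
VAL	CG2	LCD
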