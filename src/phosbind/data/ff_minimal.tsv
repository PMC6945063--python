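# phosbind minimal fixed-point-charge parameter set, v1
# Heavy-atom (united-style) point charges chosen so that every residue sums
# exactly to its formal charge (backbone N/CA/C/O sums to zero); radii and
# Lennard-Jones parameters are element-based round numbers. This table is a
# self-contained reduced parameterization written for this package so that
# all energetics are reproducible from the repository alone; it is NOT a
# port of any published force field.
# The wildcard row (res *, atom H) matches any hydrogen: zero charge, zero
# radius (hydrogens carry no surface and no charge in this reduced set).
# columns: res_name	atom_name	charge	radius	lj_epsilon	lj_sigma
# units:   -	-	e	angstrom	kJ/mol	angstrom
*	H	0.00	0.00	0.06	1.00
ALA	N	-0.30	1.65	0.70	3.25
ALA	CA	0.30	1.90	0.45	3.40
ALA	C	0.55	1.90	0.45	3.40
ALA	O	-0.55	1.60	0.85	3.00
ALA	CB	0.00	1.90	0.45	3.40
ARG	N	-0.30	1.65	0.70	3.25
ARG	CA	0.30	1.90	0.45	3.40
ARG	C	0.55	1.90	0.45	3.40
ARG	O	-0.55	1.60	0.85	3.00
ARG	CB	0.00	1.90	0.45	3.40
ARG	CG	0.00	1.90	0.45	3.40
ARG	CD	0.10	1.90	0.45	3.40
ARG	NE	-0.40	1.65	0.70	3.25
ARG	CZ	0.80	1.90	0.45	3.40
ARG	NH1	0.25	1.65	0.70	3.25
ARG	NH2	0.25	1.65	0.70	3.25
ASN	N	-0.30	1.65	0.70	3.25
ASN	CA	0.30	1.90	0.45	3.40
ASN	C	0.55	1.90	0.45	3.40
ASN	O	-0.55	1.60	0.85	3.00
ASN	CB	0.00	1.90	0.45	3.40
ASN	CG	0.55	1.90	0.45	3.40
ASN	OD1	-0.55	1.60	0.85	3.00
ASN	ND2	0.00	1.65	0.70	3.25
ASP	N	-0.30	1.65	0.70	3.25
ASP	CA	0.30	1.90	0.45	3.40
ASP	C	0.55	1.90	0.45	3.40
ASP	O	-0.55	1.60	0.85	3.00
ASP	CB	0.00	1.90	0.45	3.40
ASP	CG	0.36	1.90	0.45	3.40
ASP	OD1	-0.68	1.60	0.85	3.00
ASP	OD2	-0.68	1.60	0.85	3.00
CYS	N	-0.30	1.65	0.70	3.25
CYS	CA	0.30	1.90	0.45	3.40
CYS	C	0.55	1.90	0.45	3.40
CYS	O	-0.55	1.60	0.85	3.00
CYS	CB	0.10	1.90	0.45	3.40
CYS	SG	-0.10	2.00	1.05	3.55
GLN	N	-0.30	1.65	0.70	3.25
GLN	CA	0.30	1.90	0.45	3.40
GLN	C	0.55	1.90	0.45	3.40
GLN	O	-0.55	1.60	0.85	3.00
GLN	CB	0.00	1.90	0.45	3.40
GLN	CG	0.00	1.90	0.45	3.40
GLN	CD	0.55	1.90	0.45	3.40
GLN	OE1	-0.55	1.60	0.85	3.00
GLN	NE2	0.00	1.65	0.70	3.25
GLU	N	-0.30	1.65	0.70	3.25
GLU	CA	0.30	1.90	0.45	3.40
GLU	C	0.55	1.90	0.45	3.40
GLU	O	-0.55	1.60	0.85	3.00
GLU	CB	0.00	1.90	0.45	3.40
GLU	CG	0.00	1.90	0.45	3.40
GLU	CD	0.36	1.90	0.45	3.40
GLU	OE1	-0.68	1.60	0.85	3.00
GLU	OE2	-0.68	1.60	0.85	3.00
GLY	N	-0.30	1.65	0.70	3.25
GLY	CA	0.30	1.90	0.45	3.40
GLY	C	0.55	1.90	0.45	3.40
GLY	O	-0.55	1.60	0.85	3.00
HIS	N	-0.30	1.65	0.70	3.25
HIS	CA	0.30	1.90	0.45	3.40
HIS	C	0.55	1.90	0.45	3.40
HIS	O	-0.55	1.60	0.85	3.00
HIS	CB	0.00	1.90	0.45	3.40
HIS	CG	0.10	1.90	0.45	3.40
HIS	ND1	-0.40	1.65	0.70	3.25
HIS	CD2	0.10	1.90	0.45	3.40
HIS	CE1	0.30	1.90	0.45	3.40
HIS	NE2	-0.10	1.65	0.70	3.25
ILE	N	-0.30	1.65	0.70	3.25
ILE	CA	0.30	1.90	0.45	3.40
ILE	C	0.55	1.90	0.45	3.40
ILE	O	-0.55	1.60	0.85	3.00
ILE	CB	0.00	1.90	0.45	3.40
ILE	CG1	0.00	1.90	0.45	3.40
ILE	CG2	0.00	1.90	0.45	3.40
ILE	CD1	0.00	1.90	0.45	3.40
ILE	CD	0.00	1.90	0.45	3.40
LEU	N	-0.30	1.65	0.70	3.25
LEU	CA	0.30	1.90	0.45	3.40
LEU	C	0.55	1.90	0.45	3.40
LEU	O	-0.55	1.60	0.85	3.00
LEU	CB	0.00	1.90	0.45	3.40
LEU	CG	0.00	1.90	0.45	3.40
LEU	CD1	0.00	1.90	0.45	3.40
LEU	CD2	0.00	1.90	0.45	3.40
LYS	N	-0.30	1.65	0.70	3.25
LYS	CA	0.30	1.90	0.45	3.40
LYS	C	0.55	1.90	0.45	3.40
LYS	O	-0.55	1.60	0.85	3.00
LYS	CB	0.00	1.90	0.45	3.40
LYS	CG	0.00	1.90	0.45	3.40
LYS	CD	0.00	1.90	0.45	3.40
LYS	CE	0.25	1.90	0.45	3.40
LYS	NZ	0.75	1.65	0.70	3.25
MET	N	-0.30	1.65	0.70	3.25
MET	CA	0.30	1.90	0.45	3.40
MET	C	0.55	1.90	0.45	3.40
MET	O	-0.55	1.60	0.85	3.00
MET	CB	0.00	1.90	0.45	3.40
MET	CG	0.06	1.90	0.45	3.40
MET	SD	-0.12	2.00	1.05	3.55
MET	CE	0.06	1.90	0.45	3.40
PHE	N	-0.30	1.65	0.70	3.25
PHE	CA	0.30	1.90	0.45	3.40
PHE	C	0.55	1.90	0.45	3.40
PHE	O	-0.55	1.60	0.85	3.00
PHE	CB	0.00	1.90	0.45	3.40
PHE	CG	0.00	1.90	0.45	3.40
PHE	CD1	0.00	1.90	0.45	3.40
PHE	CD2	0.00	1.90	0.45	3.40
PHE	CE1	0.00	1.90	0.45	3.40
PHE	CE2	0.00	1.90	0.45	3.40
PHE	CZ	0.00	1.90	0.45	3.40
PRO	N	-0.30	1.65	0.70	3.25
PRO	CA	0.30	1.90	0.45	3.40
PRO	C	0.55	1.90	0.45	3.40
PRO	O	-0.55	1.60	0.85	3.00
PRO	CB	0.00	1.90	0.45	3.40
PRO	CG	0.00	1.90	0.45	3.40
PRO	CD	0.00	1.90	0.45	3.40
SER	N	-0.30	1.65	0.70	3.25
SER	CA	0.30	1.90	0.45	3.40
SER	C	0.55	1.90	0.45	3.40
SER	O	-0.55	1.60	0.85	3.00
SER	CB	0.25	1.90	0.45	3.40
SER	OG	-0.25	1.60	0.85	3.00
SEP	N	-0.30	1.65	0.70	3.25
SEP	CA	0.30	1.90	0.45	3.40
SEP	C	0.55	1.90	0.45	3.40
SEP	O	-0.55	1.60	0.85	3.00
SEP	CB	0.05	1.90	0.45	3.40
SEP	OG	-0.50	1.60	0.85	3.00
SEP	P	1.30	2.10	0.85	3.70
SEP	O1P	-0.95	1.60	0.85	3.00
SEP	O2P	-0.95	1.60	0.85	3.00
SEP	O3P	-0.95	1.60	0.85	3.00
THR	N	-0.30	1.65	0.70	3.25
THR	CA	0.30	1.90	0.45	3.40
THR	C	0.55	1.90	0.45	3.40
THR	O	-0.55	1.60	0.85	3.00
THR	CB	0.25	1.90	0.45	3.40
THR	OG1	-0.25	1.60	0.85	3.00
THR	CG2	0.00	1.90	0.45	3.40
TRP	N	-0.30	1.65	0.70	3.25
TRP	CA	0.30	1.90	0.45	3.40
TRP	C	0.55	1.90	0.45	3.40
TRP	O	-0.55	1.60	0.85	3.00
TRP	CB	0.00	1.90	0.45	3.40
TRP	CG	0.00	1.90	0.45	3.40
TRP	CD1	0.06	1.90	0.45	3.40
TRP	CD2	0.00	1.90	0.45	3.40
TRP	NE1	-0.12	1.65	0.70	3.25
TRP	CE2	0.06	1.90	0.45	3.40
TRP	CE3	0.00	1.90	0.45	3.40
TRP	CZ2	0.00	1.90	0.45	3.40
TRP	CZ3	0.00	1.90	0.45	3.40
TRP	CH2	0.00	1.90	0.45	3.40
TYR	N	-0.30	1.65	0.70	3.25
TYR	CA	0.30	1.90	0.45	3.40
TYR	C	0.55	1.90	0.45	3.40
TYR	O	-0.55	1.60	0.85	3.00
TYR	CB	0.00	1.90	0.45	3.40
TYR	CG	0.00	1.90	0.45	3.40
TYR	CD1	0.00	1.90	0.45	3.40
TYR	CD2	0.00	1.90	0.45	3.40
TYR	CE1	0.00	1.90	0.45	3.40
TYR	CE2	0.00	1.90	0.45	3.40
TYR	CZ	0.25	1.90	0.45	3.40
TYR	OH	-0.25	1.60	0.85	3.00
VAL	N	-0.30	1.65	0.70	3.25
VAL	CA	0.30	1.90	0.45	3.40
VAL	C	0.55	1.90	0.45	3.40
VAL	O	-0.55	1.60	0.85	3.00
VAL	CB	0.00	1.90	0.45	3.40
VAL	CG1	0.00	1.90	0.45	3.40
VAL	CG2	0.00	1.90	0.45	3.40
NA	NA	1.00	1.90	0.20	2.60
CL	CL	-1.00	2.27	0.60	4.00
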