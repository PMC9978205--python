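# aCSM-ALL pharmacophore typing table
# residue<TAB>atom<TAB>category[,category...]
# categories: acceptor donor aromatic hydrophobic negative neutral positive sulfide
# backbone: amide N donates (except proline, no amide H); carbonyl O accepts;
# CA aliphatic; carbonyl C polar-neutral; terminal OXT carboxylate-like.
ALA	N	donor
ALA	CA	hydrophobic
ALA	C	neutral
ALA	O	acceptor
ALA	OXT	negative,acceptor
ALA	CB	hydrophobic
ARG	N	donor
ARG	CA	hydrophobic
ARG	C	neutral
ARG	O	acceptor
ARG	OXT	negative,acceptor
ARG	CB	hydrophobic
ARG	CD	hydrophobic
ARG	CG	hydrophobic
ARG	CZ	positive
ARG	NE	positive,donor
ARG	NH1	positive,donor
ARG	NH2	positive,donor
ASN	N	donor
ASN	CA	hydrophobic
ASN	C	neutral
ASN	O	acceptor
ASN	OXT	negative,acceptor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	ND2	donor
ASN	OD1	acceptor
ASP	N	donor
ASP	CA	hydrophobic
ASP	C	neutral
ASP	O	acceptor
ASP	OXT	negative,acceptor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	negative,acceptor
ASP	OD2	negative,acceptor
CYS	N	donor
CYS	CA	hydrophobic
CYS	C	neutral
CYS	O	acceptor
CYS	OXT	negative,acceptor
CYS	CB	hydrophobic
CYS	SG	sulfide
GLN	N	donor
GLN	CA	hydrophobic
GLN	C	neutral
GLN	O	acceptor
GLN	OXT	negative,acceptor
GLN	CB	hydrophobic
GLN	CD	neutral
GLN	CG	hydrophobic
GLN	NE2	donor
GLN	OE1	acceptor
GLU	N	donor
GLU	CA	hydrophobic
GLU	C	neutral
GLU	O	acceptor
GLU	OXT	negative,acceptor
GLU	CB	hydrophobic
GLU	CD	neutral
GLU	CG	hydrophobic
GLU	OE1	negative,acceptor
GLU	OE2	negative,acceptor
GLY	N	donor
GLY	CA	hydrophobic
GLY	C	neutral
GLY	O	acceptor
GLY	OXT	negative,acceptor
HIS	N	donor
HIS	CA	hydrophobic
HIS	C	neutral
HIS	O	acceptor
HIS	OXT	negative,acceptor
HIS	CB	hydrophobic
HIS	CD2	aromatic,hydrophobic
HIS	CE1	aromatic,hydrophobic
HIS	CG	aromatic,hydrophobic
HIS	ND1	aromatic,positive,donor
HIS	NE2	aromatic,positive,donor
ILE	N	donor
ILE	CA	hydrophobic
ILE	C	neutral
ILE	O	acceptor
ILE	OXT	negative,acceptor
ILE	CB	hydrophobic
ILE	CD1	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
LEU	N	donor
LEU	CA	hydrophobic
LEU	C	neutral
LEU	O	acceptor
LEU	OXT	negative,acceptor
LEU	CB	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LEU	CG	hydrophobic
LYS	N	donor
LYS	CA	hydrophobic
LYS	C	neutral
LYS	O	acceptor
LYS	OXT	negative,acceptor
LYS	CB	hydrophobic
LYS	CD	hydrophobic
LYS	CE	hydrophobic
LYS	CG	hydrophobic
LYS	NZ	positive,donor
MET	N	donor
MET	CA	hydrophobic
MET	C	neutral
MET	O	acceptor
MET	OXT	negative,acceptor
MET	CB	hydrophobic
MET	CE	hydrophobic
MET	CG	hydrophobic
MET	SD	sulfide
PHE	N	donor
PHE	CA	hydrophobic
PHE	C	neutral
PHE	O	acceptor
PHE	OXT	negative,acceptor
PHE	CB	hydrophobic
PHE	CD1	aromatic,hydrophobic
PHE	CD2	aromatic,hydrophobic
PHE	CE1	aromatic,hydrophobic
PHE	CE2	aromatic,hydrophobic
PHE	CG	aromatic,hydrophobic
PHE	CZ	aromatic,hydrophobic
PRO	N	neutral
PRO	CA	hydrophobic
PRO	C	neutral
PRO	O	acceptor
PRO	OXT	negative,acceptor
PRO	CB	hydrophobic
PRO	CD	hydrophobic
PRO	CG	hydrophobic
SER	N	donor
SER	CA	hydrophobic
SER	C	neutral
SER	O	acceptor
SER	OXT	negative,acceptor
SER	CB	hydrophobic
SER	OG	donor,acceptor
THR	N	donor
THR	CA	hydrophobic
THR	C	neutral
THR	O	acceptor
THR	OXT	negative,acceptor
THR	CB	hydrophobic
THR	CG2	hydrophobic
THR	OG1	donor,acceptor
TRP	N	donor
TRP	CA	hydrophobic
TRP	C	neutral
TRP	O	acceptor
TRP	OXT	negative,acceptor
TRP	CB	hydrophobic
TRP	CD1	aromatic,hydrophobic
TRP	CD2	aromatic,hydrophobic
TRP	CE2	aromatic,hydrophobic
TRP	CE3	aromatic,hydrophobic
TRP	CG	aromatic,hydrophobic
TRP	CH2	aromatic,hydrophobic
TRP	CZ2	aromatic,hydrophobic
TRP	CZ3	aromatic,hydrophobic
TRP	NE1	aromatic,donor
TYR	N	donor
TYR	CA	hydrophobic
TYR	C	neutral
TYR	O	acceptor
TYR	OXT	negative,acceptor
TYR	CB	hydrophobic
TYR	CD1	aromatic,hydrophobic
TYR	CD2	aromatic,hydrophobic
TYR	CE1	aromatic,hydrophobic
TYR	CE2	aromatic,hydrophobic
TYR	CG	aromatic,hydrophobic
TYR	CZ	aromatic,hydrophobic
TYR	OH	donor,acceptor
VAL	N	donor
VAL	CA	hydrophobic
VAL	C	neutral
VAL	O	acceptor
VAL	OXT	negative,acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
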