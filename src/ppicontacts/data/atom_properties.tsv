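# atom_properties.tsv  v1
# Per-residue heavy-atom van der Waals and covalent radii (Angstrom) with
# interaction-capability flags for the 20 canonical residues plus the
# chain-terminating OXT.
# Radii: residue-specific CSD-derived set (ProtOr classes); covalent radii are
# element values (C 0.77, N 0.70, O 0.66, S 1.04).
# Flags authored from fixed chemistry at pH 7: hydrophobic = carbon with no
# N/O neighbour, plus CYS SG / MET SD; aromatic = planar ring atoms of
# PHE/TYR/TRP/HIS; cationic = LYS NZ, ARG guanidinium (NE/CZ/NH1/NH2) and,
# when the his_cationic option is on, the HIS imidazole nitrogens; anionic =
# ASP/GLU carboxylates and OXT; aromatic_hb_acceptor = PHE/TYR/TRP ring atoms
# only.  Dual donor/acceptor atoms are exactly SER OG, THR OG1, HIS ND1,
# CYS SG, TRP NE1, TYR OH.  Borderline calls (MET SD hydrophobic and weak
# acceptor; HIS NE2 donor-only) follow common practice.
# PRO backbone N carries no amide hydrogen and is not a donor.
res_name	atom_name	vdw_radius	cov_radius	hydrophobic	aromatic	cationic	anionic	hb_donor	hb_acceptor	aromatic_hb_acceptor
ALA	N	1.64	0.70	0	0	0	0	1	0	0
ALA	CA	1.88	0.77	0	0	0	0	0	0	0
ALA	C	1.61	0.77	0	0	0	0	0	0	0
ALA	O	1.42	0.66	0	0	0	0	0	1	0
ALA	OXT	1.42	0.66	0	0	0	1	0	1	0
ALA	CB	1.88	0.77	1	0	0	0	0	0	0
ARG	N	1.64	0.70	0	0	0	0	1	0	0
ARG	CA	1.88	0.77	0	0	0	0	0	0	0
ARG	C	1.61	0.77	0	0	0	0	0	0	0
ARG	O	1.42	0.66	0	0	0	0	0	1	0
ARG	OXT	1.42	0.66	0	0	0	1	0	1	0
ARG	CB	1.88	0.77	1	0	0	0	0	0	0
ARG	CG	1.88	0.77	1	0	0	0	0	0	0
ARG	CD	1.88	0.77	0	0	0	0	0	0	0
ARG	NE	1.64	0.70	0	0	1	0	1	0	0
ARG	CZ	1.61	0.77	0	0	1	0	0	0	0
ARG	NH1	1.64	0.70	0	0	1	0	1	0	0
ARG	NH2	1.64	0.70	0	0	1	0	1	0	0
ASN	N	1.64	0.70	0	0	0	0	1	0	0
ASN	CA	1.88	0.77	0	0	0	0	0	0	0
ASN	C	1.61	0.77	0	0	0	0	0	0	0
ASN	O	1.42	0.66	0	0	0	0	0	1	0
ASN	OXT	1.42	0.66	0	0	0	1	0	1	0
ASN	CB	1.88	0.77	1	0	0	0	0	0	0
ASN	CG	1.61	0.77	0	0	0	0	0	0	0
ASN	OD1	1.42	0.66	0	0	0	0	0	1	0
ASN	ND2	1.64	0.70	0	0	0	0	1	0	0
ASP	N	1.64	0.70	0	0	0	0	1	0	0
ASP	CA	1.88	0.77	0	0	0	0	0	0	0
ASP	C	1.61	0.77	0	0	0	0	0	0	0
ASP	O	1.42	0.66	0	0	0	0	0	1	0
ASP	OXT	1.42	0.66	0	0	0	1	0	1	0
ASP	CB	1.88	0.77	1	0	0	0	0	0	0
ASP	CG	1.61	0.77	0	0	0	0	0	0	0
ASP	OD1	1.42	0.66	0	0	0	1	0	1	0
ASP	OD2	1.42	0.66	0	0	0	1	0	1	0
CYS	N	1.64	0.70	0	0	0	0	1	0	0
CYS	CA	1.88	0.77	0	0	0	0	0	0	0
CYS	C	1.61	0.77	0	0	0	0	0	0	0
CYS	O	1.42	0.66	0	0	0	0	0	1	0
CYS	OXT	1.42	0.66	0	0	0	1	0	1	0
CYS	CB	1.88	0.77	1	0	0	0	0	0	0
CYS	SG	1.77	1.04	1	0	0	0	1	1	0
GLN	N	1.64	0.70	0	0	0	0	1	0	0
GLN	CA	1.88	0.77	0	0	0	0	0	0	0
GLN	C	1.61	0.77	0	0	0	0	0	0	0
GLN	O	1.42	0.66	0	0	0	0	0	1	0
GLN	OXT	1.42	0.66	0	0	0	1	0	1	0
GLN	CB	1.88	0.77	1	0	0	0	0	0	0
GLN	CG	1.88	0.77	1	0	0	0	0	0	0
GLN	CD	1.61	0.77	0	0	0	0	0	0	0
GLN	OE1	1.42	0.66	0	0	0	0	0	1	0
GLN	NE2	1.64	0.70	0	0	0	0	1	0	0
GLU	N	1.64	0.70	0	0	0	0	1	0	0
GLU	CA	1.88	0.77	0	0	0	0	0	0	0
GLU	C	1.61	0.77	0	0	0	0	0	0	0
GLU	O	1.42	0.66	0	0	0	0	0	1	0
GLU	OXT	1.42	0.66	0	0	0	1	0	1	0
GLU	CB	1.88	0.77	1	0	0	0	0	0	0
GLU	CG	1.88	0.77	1	0	0	0	0	0	0
GLU	CD	1.61	0.77	0	0	0	0	0	0	0
GLU	OE1	1.42	0.66	0	0	0	1	0	1	0
GLU	OE2	1.42	0.66	0	0	0	1	0	1	0
GLY	N	1.64	0.70	0	0	0	0	1	0	0
GLY	CA	1.88	0.77	0	0	0	0	0	0	0
GLY	C	1.61	0.77	0	0	0	0	0	0	0
GLY	O	1.42	0.66	0	0	0	0	0	1	0
GLY	OXT	1.42	0.66	0	0	0	1	0	1	0
HIS	N	1.64	0.70	0	0	0	0	1	0	0
HIS	CA	1.88	0.77	0	0	0	0	0	0	0
HIS	C	1.61	0.77	0	0	0	0	0	0	0
HIS	O	1.42	0.66	0	0	0	0	0	1	0
HIS	OXT	1.42	0.66	0	0	0	1	0	1	0
HIS	CB	1.88	0.77	1	0	0	0	0	0	0
HIS	CG	1.61	0.77	0	1	0	0	0	0	0
HIS	ND1	1.64	0.70	0	1	1	0	1	1	0
HIS	CD2	1.76	0.77	0	1	0	0	0	0	0
HIS	CE1	1.76	0.77	0	1	0	0	0	0	0
HIS	NE2	1.64	0.70	0	1	1	0	1	0	0
ILE	N	1.64	0.70	0	0	0	0	1	0	0
ILE	CA	1.88	0.77	0	0	0	0	0	0	0
ILE	C	1.61	0.77	0	0	0	0	0	0	0
ILE	O	1.42	0.66	0	0	0	0	0	1	0
ILE	OXT	1.42	0.66	0	0	0	1	0	1	0
ILE	CB	1.88	0.77	1	0	0	0	0	0	0
ILE	CG1	1.88	0.77	1	0	0	0	0	0	0
ILE	CG2	1.88	0.77	1	0	0	0	0	0	0
ILE	CD1	1.88	0.77	1	0	0	0	0	0	0
LEU	N	1.64	0.70	0	0	0	0	1	0	0
LEU	CA	1.88	0.77	0	0	0	0	0	0	0
LEU	C	1.61	0.77	0	0	0	0	0	0	0
LEU	O	1.42	0.66	0	0	0	0	0	1	0
LEU	OXT	1.42	0.66	0	0	0	1	0	1	0
LEU	CB	1.88	0.77	1	0	0	0	0	0	0
LEU	CG	1.88	0.77	1	0	0	0	0	0	0
LEU	CD1	1.88	0.77	1	0	0	0	0	0	0
LEU	CD2	1.88	0.77	1	0	0	0	0	0	0
LYS	N	1.64	0.70	0	0	0	0	1	0	0
LYS	CA	1.88	0.77	0	0	0	0	0	0	0
LYS	C	1.61	0.77	0	0	0	0	0	0	0
LYS	O	1.42	0.66	0	0	0	0	0	1	0
LYS	OXT	1.42	0.66	0	0	0	1	0	1	0
LYS	CB	1.88	0.77	1	0	0	0	0	0	0
LYS	CG	1.88	0.77	1	0	0	0	0	0	0
LYS	CD	1.88	0.77	1	0	0	0	0	0	0
LYS	CE	1.88	0.77	0	0	0	0	0	0	0
LYS	NZ	1.64	0.70	0	0	1	0	1	0	0
MET	N	1.64	0.70	0	0	0	0	1	0	0
MET	CA	1.88	0.77	0	0	0	0	0	0	0
MET	C	1.61	0.77	0	0	0	0	0	0	0
MET	O	1.42	0.66	0	0	0	0	0	1	0
MET	OXT	1.42	0.66	0	0	0	1	0	1	0
MET	CB	1.88	0.77	1	0	0	0	0	0	0
MET	CG	1.88	0.77	1	0	0	0	0	0	0
MET	SD	1.77	1.04	1	0	0	0	0	1	0
MET	CE	1.88	0.77	1	0	0	0	0	0	0
PHE	N	1.64	0.70	0	0	0	0	1	0	0
PHE	CA	1.88	0.77	0	0	0	0	0	0	0
PHE	C	1.61	0.77	0	0	0	0	0	0	0
PHE	O	1.42	0.66	0	0	0	0	0	1	0
PHE	OXT	1.42	0.66	0	0	0	1	0	1	0
PHE	CB	1.88	0.77	1	0	0	0	0	0	0
PHE	CG	1.61	0.77	1	1	0	0	0	0	1
PHE	CD1	1.76	0.77	1	1	0	0	0	0	1
PHE	CD2	1.76	0.77	1	1	0	0	0	0	1
PHE	CE1	1.76	0.77	1	1	0	0	0	0	1
PHE	CE2	1.76	0.77	1	1	0	0	0	0	1
PHE	CZ	1.76	0.77	1	1	0	0	0	0	1
PRO	N	1.64	0.70	0	0	0	0	0	0	0
PRO	CA	1.88	0.77	0	0	0	0	0	0	0
PRO	C	1.61	0.77	0	0	0	0	0	0	0
PRO	O	1.42	0.66	0	0	0	0	0	1	0
PRO	OXT	1.42	0.66	0	0	0	1	0	1	0
PRO	CB	1.88	0.77	1	0	0	0	0	0	0
PRO	CG	1.88	0.77	1	0	0	0	0	0	0
PRO	CD	1.88	0.77	0	0	0	0	0	0	0
SER	N	1.64	0.70	0	0	0	0	1	0	0
SER	CA	1.88	0.77	0	0	0	0	0	0	0
SER	C	1.61	0.77	0	0	0	0	0	0	0
SER	O	1.42	0.66	0	0	0	0	0	1	0
SER	OXT	1.42	0.66	0	0	0	1	0	1	0
SER	CB	1.88	0.77	0	0	0	0	0	0	0
SER	OG	1.46	0.66	0	0	0	0	1	1	0
THR	N	1.64	0.70	0	0	0	0	1	0	0
THR	CA	1.88	0.77	0	0	0	0	0	0	0
THR	C	1.61	0.77	0	0	0	0	0	0	0
THR	O	1.42	0.66	0	0	0	0	0	1	0
THR	OXT	1.42	0.66	0	0	0	1	0	1	0
THR	CB	1.88	0.77	0	0	0	0	0	0	0
THR	OG1	1.46	0.66	0	0	0	0	1	1	0
THR	CG2	1.88	0.77	1	0	0	0	0	0	0
TRP	N	1.64	0.70	0	0	0	0	1	0	0
TRP	CA	1.88	0.77	0	0	0	0	0	0	0
TRP	C	1.61	0.77	0	0	0	0	0	0	0
TRP	O	1.42	0.66	0	0	0	0	0	1	0
TRP	OXT	1.42	0.66	0	0	0	1	0	1	0
TRP	CB	1.88	0.77	1	0	0	0	0	0	0
TRP	CG	1.61	0.77	1	1	0	0	0	0	1
TRP	CD1	1.76	0.77	0	1	0	0	0	0	1
TRP	CD2	1.61	0.77	1	1	0	0	0	0	1
TRP	NE1	1.64	0.70	0	1	0	0	1	1	1
TRP	CE2	1.61	0.77	0	1	0	0	0	0	1
TRP	CE3	1.76	0.77	1	1	0	0	0	0	1
TRP	CZ2	1.76	0.77	1	1	0	0	0	0	1
TRP	CZ3	1.76	0.77	1	1	0	0	0	0	1
TRP	CH2	1.76	0.77	1	1	0	0	0	0	1
TYR	N	1.64	0.70	0	0	0	0	1	0	0
TYR	CA	1.88	0.77	0	0	0	0	0	0	0
TYR	C	1.61	0.77	0	0	0	0	0	0	0
TYR	O	1.42	0.66	0	0	0	0	0	1	0
TYR	OXT	1.42	0.66	0	0	0	1	0	1	0
TYR	CB	1.88	0.77	1	0	0	0	0	0	0
TYR	CG	1.61	0.77	1	1	0	0	0	0	1
TYR	CD1	1.76	0.77	1	1	0	0	0	0	1
TYR	CD2	1.76	0.77	1	1	0	0	0	0	1
TYR	CE1	1.76	0.77	1	1	0	0	0	0	1
TYR	CE2	1.76	0.77	1	1	0	0	0	0	1
TYR	CZ	1.61	0.77	0	1	0	0	0	0	1
TYR	OH	1.46	0.66	0	0	0	0	1	1	0
VAL	N	1.64	0.70	0	0	0	0	1	0	0
VAL	CA	1.88	0.77	0	0	0	0	0	0	0
VAL	C	1.61	0.77	0	0	0	0	0	0	0
VAL	O	1.42	0.66	0	0	0	0	0	1	0
VAL	OXT	1.42	0.66	0	0	0	1	0	1	0
VAL	CB	1.88	0.77	1	0	0	0	0	0	0
VAL	CG1	1.88	0.77	1	0	0	0	0	0	0
VAL	CG2	1.88	0.77	1	0	0	0	0	0	0
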