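# graphpka ionizable-site pattern table, version 1
# Matched in order on the neutral form; an atom keeps its first assignment.
# site_index: position of the ionizable atom within the SMARTS match.
# carbon_only: matched only when carbon acidic centers are enabled.
# Deliberate exclusions: sp3 alcohols (pKa typically > 14) and terminal
# amides are not ionization centers; only activated (imide-like) N-H is.
name	smarts	role	group_class	site_index	carbon_only
carboxylic_acid	[CX3](=[OX1])[OX2H1]	acidic	carboxylic_acid	2	no
sulfonic_acid	[SX4](=[OX1])(=[OX1])[OX2H1]	acidic	sulfonic_acid	3	no
phosphonic_acid	[PX4](=[OX1])[OX2H1]	acidic	phosphonic_acid	2	no
phenol	[c][OX2H1]	acidic	phenol	1	no
thiol	[SX2H1]	acidic	thiol	0	no
imide	[NX3H1]([CX3]=[OX1])[CX3]=[OX1]	acidic	imide	0	no
sulfonamide	[NX3;H1,H2][SX4](=[OX1])=[OX1]	acidic	sulfonamide	0	no
azole_nh	[nX3H1]	acidic	azole	0	no
activated_ch	[CX4;H1,H2]([CX3]=[OX1])[CX3]=[OX1]	acidic	activated_carbon	0	yes
amidine	[NX2;+0]=[CX3][NX3;+0]	basic	amidine	0	no
aniline	[NX3;H2,H1;+0][c]	basic	aniline	0	no
aliphatic_amine	[NX3;+0;!$([NX3][CX3]=[OX1]);!$([NX3][CX3]=[SX1]);!$([NX3][CX3]=[NX2]);!$([NX3][SX4](=[OX1])=[OX1]);!$([NX3][NX2]=[OX1]);!$([NX3][c])]	basic	aliphatic_amine	0	no
pyridine_n	[nX2;H0;+0]	basic	pyridine	0	no
imine	[NX2;H1,H0;+0]=[CX3]	basic	imine	0	no
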