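# Residue-by-heptad-position coiled-coil propensity table (madsbox v1).
# Values are relative enrichments of each residue at heptad positions a-g in
# dimeric coiled-coils versus globular sequence, authored for this package in
# the style of the MTIDK statistics of the COILS method (hydrophobic residues
# enriched at the core a/d positions, charged/polar residues at b,c,e,f,g,
# proline strongly depleted everywhere).  Window scores are weighted
# geometric means of these values.
residue	a	b	c	d	e	f	g
L	3.00	0.60	0.60	3.40	0.70	0.60	0.70
I	2.60	0.40	0.40	1.40	0.50	0.40	0.50
V	2.20	0.50	0.50	1.40	0.50	0.50	0.60
M	2.40	0.80	0.80	2.60	0.80	0.80	0.80
F	1.20	0.60	0.60	1.00	0.60	0.60	0.60
A	1.60	1.20	1.20	1.60	1.20	1.20	1.20
K	0.70	1.40	1.40	0.60	1.60	1.40	1.50
R	0.80	1.30	1.30	0.70	1.50	1.30	1.40
E	0.90	1.50	1.50	0.80	1.70	1.50	1.60
Q	1.00	1.40	1.40	0.90	1.50	1.40	1.50
D	0.40	1.20	1.20	0.40	1.10	1.20	1.10
N	0.80	1.00	1.00	0.70	1.00	1.00	1.00
S	0.70	1.00	1.00	0.70	0.90	1.00	0.90
T	0.80	0.90	0.90	0.80	0.90	0.90	0.90
H	0.60	0.90	0.90	0.60	0.90	0.90	0.90
C	0.70	0.60	0.60	0.70	0.60	0.60	0.60
W	0.60	0.50	0.50	0.60	0.50	0.50	0.50
Y	0.80	0.70	0.70	0.80	0.70	0.70	0.70
G	0.30	0.60	0.60	0.30	0.60	0.60	0.60
P	0.05	0.10	0.10	0.05	0.10	0.10	0.10
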