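# Per-amino-acid biophysical property scales used to build reduced alphabets.
# Sources: polarity — Grantham, Science 185:862 (1974);
# solvation_free_energy (kcal/mol) — Eisenberg & McLachlan, Nature 319:199 (1986);
# vdw_volume_normalized — Fauchere et al., Int J Pept Protein Res 32:269 (1988);
# radius_of_gyration_sidechain (A) — Levitt, J Mol Biol 104:59 (1976);
# asa_tripeptide (A^2) — Chothia, J Mol Biol 105:1 (1976).
amino_acid	polarity	solvation_free_energy	vdw_volume_normalized	radius_of_gyration_sidechain	asa_tripeptide
A	8.1	0.67	1.00	0.77	115
C	5.5	0.38	2.43	1.22	135
D	13.0	-1.20	2.78	1.43	150
E	12.3	-0.76	3.78	1.77	190
F	5.2	2.30	5.89	1.90	210
G	9.0	0.00	0.00	0.58	75
H	10.4	0.64	4.66	1.78	195
I	5.2	1.90	4.00	1.56	175
K	11.3	-0.57	4.77	2.08	200
L	4.9	1.90	4.00	1.54	170
M	5.7	2.40	4.43	1.80	185
N	11.6	-0.60	2.95	1.45	160
P	8.0	1.20	2.72	1.25	145
Q	10.5	-0.22	3.95	1.75	180
R	10.5	-2.10	6.13	2.38	225
S	9.2	0.01	1.60	1.08	115
T	8.6	0.52	2.60	1.24	140
V	5.9	1.50	3.00	1.29	155
W	5.4	2.60	8.08	2.21	255
Y	6.2	1.60	6.47	2.13	230
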