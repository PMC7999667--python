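# Six physicochemical property scales over the 20 canonical amino acids.
# Columns: residues in alphabetical one-letter order. Sources:
# hydrophobicity: Tanford-derived scale as conventional in PseAAC encodings (Tanford 1962; Chou 2001)
# hydrophilicity: Hopp & Woods (1981) PNAS 78:3824
# mass: side-chain mass in Da (residue mass minus the Gly backbone), standard PseAAC convention
# pK1: alpha-carboxyl pKa at 25 C, standard biochemistry tables (Lehninger/CRC)
# pK2: alpha-amino pKa at 25 C, standard biochemistry tables (Lehninger/CRC)
# pI: isoelectric point at 25 C, standard biochemistry tables (Lehninger/CRC)
property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
mass	15.0	47.0	59.0	73.0	91.0	1.0	82.0	57.0	73.0	57.0	75.0	58.0	42.0	72.0	101.0	31.0	45.0	43.0	130.0	107.0
pK1	2.34	1.96	1.88	2.19	1.83	2.34	1.82	2.36	2.18	2.36	2.28	2.02	1.99	2.17	2.17	2.21	2.09	2.32	2.83	2.20
pK2	9.69	10.28	9.60	9.67	9.13	9.60	9.17	9.60	8.95	9.60	9.21	8.80	10.60	9.13	9.04	9.15	9.10	9.62	9.39	9.11
pI	6.00	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
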