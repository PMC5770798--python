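aa	hydrophobicity	hydrophilicity	side_chain_mass	kyte_doolittle	grantham_polarity
A	0.62	-0.5	15.0	1.8	8.1
C	0.29	-1.0	47.0	2.5	5.5
D	-0.90	3.0	59.0	-3.5	13.0
E	-0.74	3.0	73.0	-3.5	12.3
F	1.19	-2.5	91.0	2.8	5.2
G	0.48	0.0	1.0	-0.4	9.0
H	-0.40	-0.5	82.0	-3.2	10.4
I	1.38	-1.8	57.0	4.5	5.2
K	-1.50	3.0	73.0	-3.9	11.3
L	1.06	-1.8	57.0	3.8	4.9
M	0.64	-1.3	75.0	1.9	5.7
N	-0.78	0.2	58.0	-3.5	11.6
P	0.12	0.0	42.0	-1.6	8.0
Q	-0.85	0.2	72.0	-3.5	10.5
R	-2.53	3.0	101.0	-4.5	10.5
S	-0.18	0.3	31.0	-0.8	9.2
T	-0.05	-0.4	45.0	-0.7	8.6
V	1.08	-1.5	43.0	4.2	5.9
W	0.81	-3.4	130.0	-0.9	5.4
Y	0.26	-2.3	107.0	-1.3	6.2
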