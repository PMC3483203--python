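# Normalized dinucleotide physicochemical scales (canonical package constants).
# Column order is frozen and defines feature-block order in the concatenated
# profile encoding:
#   P1  A-philicity
#   P2  base stacking
#   P3  B-DNA twist
#   P4  bendability
#   P5  DNA bending stiffness
#   P6  DNA denaturation
#   P7  duplex disrupt energy
#   P8  duplex free energy
#   P9  propeller twist
#   P10 protein deformation
#   P11 protein-DNA twist
#   P12 Z-DNA
# Values are dimensionless, roughly min-max scaled to [-1, 1]; a few cells
# exceed 1 (e.g. TA bendability 2.37) and are shipped verbatim as constants.
dinucleotide	P1	P2	P3	P4	P5	P6	P7	P8	P9	P10	P11	P12
AA	0.85	0.85	-0.22	-0.96	-0.73	-0.62	-0.09	0.68	-1.00	1.00	0.36	0.23
AC	-1.00	-1.00	-0.60	-0.45	-0.27	0.37	-0.64	0.37	0.05	0.56	-0.48	0.50
AG	-0.56	-0.56	-1.00	0.45	-0.27	-0.18	-0.36	0.37	-0.12	-0.10	-0.39	0.04
AT	-0.01	-0.01	1.00	-1.00	-1.00	-0.48	-1.00	1.00	-0.31	-0.90	-1.00	1.00
CA	1.00	1.00	0.13	1.00	-0.27	-0.65	-0.09	0.16	0.75	-0.14	0.88	-0.77
CC	-0.87	-0.87	-0.25	0.81	1.00	0.15	1.00	-0.47	1.00	-0.75	-0.15	-0.35
CG	-0.14	-0.14	-0.89	0.80	0.18	-0.10	1.45	-1.00	0.64	-0.45	0.60	-1.00
CT	-0.56	-0.56	-1.00	-0.29	-0.27	-0.18	-0.36	0.37	-0.12	-1.00	-0.39	0.04
GA	0.87	0.87	0.43	1.24	-0.27	-0.30	-0.36	0.37	-0.02	-0.87	0.65	0.04
GC	0.32	0.32	0.24	1.17	0.18	1.00	1.00	-0.47	0.44	-0.54	0.01	0.27
GG	-0.87	-0.87	-0.25	0.63	1.00	0.15	1.00	-0.47	1.00	-0.14	-0.15	-0.35
GT	-1.00	-1.00	-0.60	-0.29	-0.27	0.37	-0.64	0.37	0.05	-0.90	-0.48	0.50
TA	0.32	0.32	-0.84	2.37	-1.00	-1.00	-0.45	1.00	0.29	-0.87	1.00	-0.31
TC	0.87	0.87	0.43	0.24	-0.27	-0.30	-0.36	0.37	-0.02	-0.45	0.65	0.04
TG	1.00	1.00	0.13	2.02	-0.27	-0.65	-0.09	0.16	0.75	0.56	0.88	-0.77
TT	0.85	0.85	-0.22	-1.00	-0.73	-0.62	-0.09	0.68	-1.00	-0.77	0.36	0.23
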