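# RNA dinucleotide helical physicochemical parameters (Twist, Tilt, Roll,
# Shift, Slide, Rise) as conventionally distributed with iLearn/Pse-in-One
# style RNA descriptor tool kits (values rounded as in common distributions).
# Columns are standardized to mean 0 / variance 1 over the 16 dinucleotides
# at load time, so descriptor outputs are invariant to affine rescaling of
# this raw table.
dinucleotide	Twist	Tilt	Roll	Shift	Slide	Rise
AA	31	-0.8	7.0	-0.08	-1.27	3.18
AC	32	0.8	4.8	0.23	-1.43	3.24
AG	30	0.5	8.5	-0.04	-1.50	3.30
AU	33	1.1	7.1	-0.06	-1.36	3.24
CA	31	1.0	9.9	0.11	-1.46	3.09
CC	32	0.3	8.7	-0.01	-1.78	3.32
CG	27	-0.1	12.1	0.30	-1.89	3.30
CU	30	0.5	8.5	-0.04	-1.50	3.30
GA	32	1.3	9.4	0.07	-1.70	3.38
GC	35	0.0	6.1	0.07	-1.39	3.22
GG	32	0.3	12.1	-0.01	-1.78	3.32
GU	32	0.8	4.8	0.23	-1.43	3.24
UA	32	-0.2	10.7	-0.02	-1.45	3.26
UC	32	1.3	9.4	0.07	-1.70	3.38
UG	31	1.0	9.9	0.11	-1.46	3.09
UU	31	-0.8	7.0	-0.08	-1.27	3.18
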