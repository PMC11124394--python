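descriptor	SW480	SW620	PC3	HepG2	MDA	A549	HaCaT
BE_w	0.59	0.62	0.63	0.62	0.64	0.63	0.51
MLogP	3.1e-5	1.4e-5	1.8e-3	3.1e-4	4.7e-3	5.2e-5	2.5e-4
TPSA	0.25	0.25	0.24	0.25	0.30	0.30	0.28
HBD	0.32	0.36	0.39	0.41	0.42	0.43	0.38
POL	7.5e-5	4.4e-6	1.4e-3	4e-4	5e-3	1.6e-4	7.6e-4
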