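compound	SW480	SW620	PC3	HepG2	MDA	A549	HaCaT
4	−8.10	−8.16	−8.09	−8.14	−8.04	−8.08	−8.08
5	−8.43	−8.49	−8.43	−8.48	−8.38	−8.41	−8.41
8	−7.68	−7.75	−7.67	−7.75	−7.62	−7.65	−7.69
10	−8.48	−8.52	−8.48	−8.51	−8.44	−8.47	−8.44
11	−8.56	−8.60	−8.55	−8.58	−8.52	−8.55	−8.52
13	−8.47	−8.53	−8.47	−8.51	−8.42	−8.46	−8.42
16	−8.64	−8.67	−8.63	−8.62	−8.61	−8.63	−8.58
18	−8.56	−8.60	−8.56	−8.54	−8.53	−8.55	−8.50
20	−8.46	−8.50	−8.46	−8.47	−8.43	−8.45	−8.40
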