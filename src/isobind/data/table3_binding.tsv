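compound	αβI	αβIIa	αβIIb	αβIII	αβIVa	αβIVb	αβV	αβVI	αβVIII
4	−8.69	−8.35	−8.4	−8.67	−8.63	−8.52	−8.21	−8.81	−8.9
5	−9.32	−8.96	−8.95	−9.16	−9.21	−9.1	−8.8	−9.5	−9.46
8	−7.83	−7.66	−7.57	−7.85	−7.79	−7.72	−7.12	−7.98	−7.9
10	−8.56	−8.51	−8.53	−8.34	−8.78	−8.63	−8.34	−8.44	−8.58
11	−9	−8.82	−8.84	−8.86	−9.16	−9.14	−8.82	−8.89	−8.92
13	−8.67	−8.48	−8.16	−8.99	−8.85	−8.49	−8.47	−8.92	−8.98
16	−9.56	−8.91	−9.23	−8.95	−9.47	−9.32	−9.12	−9.49	−8.98
18	−8.52	−9.63	−9.36	−9.36	−9.57	−9.73	−8.92	−9.28	−9.2
20	−7.94	−7.59	−7.57	−7.76	−7.98	−8.13	−8.06	−7.82	−7.59
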