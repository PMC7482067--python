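host	unique_viruses
S00	1
S01	1
S02	1
S03	1
S04	1
S05	1
S06	1
S07	1
S08	1
S09	1
S10	1
S11	1
S12	1
S13	1
S14	1
S15	1
S16	1
S17	1
S18	2
S19	2
S20	2
S21	2
S22	2
S23	2
S24	2
S25	2
S26	2
S27	2
S28	3
S29	3
S30	4
S31	5
S32	6
S33	7
S34	8
S35	11
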