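F1	A07	0	0	1	1
F1	A06	0	0	2	2
F1	A03	A07	A06	1	1
F1	A08	A07	A06	2	2
F1	A12	A07	A06	1	2
F1	A15	A07	A06	2	2
F1	A23	A07	A06	2	2
F1	A09	0	0	2	1
F1	A10	0	0	1	1
F1	A11	0	0	2	1
F1	A13	0	0	1	1
F1	A14	0	0	1	1
F1	A17	A03	A09	1	2
F1	A18	A03	A09	1	2
F1	A21	A10	A08	1	2
F1	A16	A10	A08	2	1
F1	A25	A12	A11	1	2
F1	A20	A12	A11	2	1
F1	A22	A13	A15	1	1
F1	A28	A13	A15	2	1
F1	A29	A14	A23	1	1
F1	A30	A14	A23	2	1
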