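rank	locus	gene	overall_score	ann_score	popu_score	seg_score_dom	seg_score	region	dbsnp_id	variant_type	af_1000g
1	chr9;128305252;128305252;C;G	MAPKAP1	0.0002	0.01	0.02	1	0.001953	intronic	rs78809014	SNV	0.008786
2	chr21;14982716;14982716;T;C	POTED	4.80E-07	0.8	0.6	1.00E-06	0.001953	exonic	rs201206142	SNV	-
3	chr5;115346245;115346245;T;G	LVRN	3.84E-08	1	0.6	6.40E-08	0.001953	intronic	rs17138646	SNV	-
4	chr16;33629700;33629700;G;A	-	6.00E-09	0.01	0.6	1.00E-06	0.001953	intergenic	rs2019670	SNV	-
5	chr14;77579754;77579754;T;C	CIPC	1.02E-09	0.01	0.02	5.12E-06	0.007813	intronic	rs74069037	SNV	0.023962
6	chr22;22730853;22730853;G;GCC	-	1.00E-09	0.01	1	1.00E-07	0.001953	intergenic	-	indel	-
7	chr22;22730849;22730849;GTA;G	-	1.00E-09	0.01	1	1.00E-07	0.001953	intergenic	-	indel	-
8	chr22;22730891;22730891;G;C	-	6.00E-10	0.01	0.6	1.00E-07	0.001953	intergenic	rs201626791	SNV	-
9	chr22;22730869;22730869;G;A	-	6.00E-10	0.01	0.6	1.00E-07	0.001953	intergenic	rs114666913	SNV	-
10	chr22;22730860;22730860;C;T	-	6.00E-10	0.01	0.6	1.00E-07	0.001953	intergenic	rs117244515	SNV	-
11	chr16;33630022;33630022;A;T	-	6.00E-10	0.01	0.6	1.00E-07	0.001953	intergenic	rs2075113	SNV	-
12	chr16;33534209;33534209;T;A	LOC102724207	6.00E-10	0.01	0.6	1.00E-07	0.001953	ncRNA_intronic	rs111304289	SNV	-
13	chr2;170633023;170633023;T;TA	-	3.84E-10	0.01	0.6	6.40E-08	0.001953	intergenic	rs11422611	indel	-
14	chr22;22730829;22730829;G;A	-	2.00E-10	0.01	0.2	1.00E-07	0.001953	intergenic	rs140157920	SNV	0.000399
15	chr16;33402061;33402061;G;A	-	2.00E-10	0.01	0.02	1.00E-06	0.001953	intergenic	rs8047387	SNV	-
16	chr16;33534205;33534205;T;C	LOC102724207	6.00E-11	0.01	0.6	1.00E-08	0.001953	ncRNA_intronic	rs75274563	SNV	-
17	chr21;28215826;28215826;C;CACA	ADAMTS1	3.07E-11	0.01	0.6	5.12E-09	0.007813	intronic	rs373460567	indel	-
18	chr2;136530157;136530157;G;A	UBXN4	1.28E-11	0.01	0.02	6.40E-08	0.003906	intronic	rs78878675	SNV	0.039736
19	chr2;136511886;136511886;G;A	UBXN4	1.28E-11	0.01	0.02	6.40E-08	0.003906	intronic	rs74265494	SNV	0.039736
20	chr16;71100830;71100830;T;C	HYDIN	6.00E-12	0.01	0.6	1.00E-09	0.001953	intronic	rs146519470	SNV	-
21	chr2;227966298;227966298;T;TA	COL4A4	5.24E-12	0.01	0.2	2.62E-09	0.03125	intronic	rs59443812	indel	-
22	chr19;33490480;33490480;G;A	RHPN2	2.00E-12	0.01	0.2	1.00E-09	0.001953	intronic	rs74603434	SNV	-
23	chr14;106994063;106994063;C;T	-	4.80E-13	0.01	0.6	8.00E-11	0.000977	intergenic	rs4774148	SNV	-
24	chr3;129108158;129108158;A;AG	RPL32P3	1.57E-14	0.01	0.6	2.62E-12	0.015625	ncRNA_intronic	rs58915955	indel	-
25	chr17;12859125;12859125;C;CG	ARHGAP44	1.01E-16	0.01	0.6	1.68E-14	0.03125	intronic	rs3214256	indel	-
26	chr21;45649494;45649494;A;G	ICOSLG	8.05E-21	0.01	0.6	1.34E-18	0.003906	intronic	rs7278772	SNV	-
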