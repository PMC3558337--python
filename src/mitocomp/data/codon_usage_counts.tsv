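codon	aa	bx_count	pv_count	bx_pct	pv_pct
TTT	Phe	649	483	19.12	14.49
TTC	Phe	18	38	0.53	1.14
TTA	Leu	459	377	13.52	11.31
TTG	Leu	73	107	2.15	3.21
CTT	Leu	26	46	0.77	1.38
CTC	Leu	2	1	0.06	0.03
CTA	Leu	12	33	0.35	0.99
CTG	Leu	0	8	0.00	0.24
ATT	Ile	260	188	7.66	5.64
ATC	Ile	6	13	0.18	0.39
ATA	Met	129	166	3.80	4.98
ATG	Met	17	19	0.50	0.57
GTT	Val	125	143	3.68	4.29
GTC	Val	2	8	0.06	0.24
GTA	Val	91	78	2.68	2.34
GTG	Val	22	19	0.65	0.57
TCT	Ser	85	90	2.50	2.70
TCC	Ser	1	13	0.03	0.39
TCA	Ser	29	38	0.85	1.14
TCG	Ser	3	7	0.09	0.21
CCT	Pro	49	41	1.44	1.23
CCC	Pro	1	4	0.03	0.12
CCA	Pro	16	28	0.47	0.84
CCG	Pro	3	4	0.09	0.12
ACT	Thr	67	62	1.97	1.86
ACC	Thr	0	13	0.00	0.39
ACA	Thr	18	30	0.53	0.90
ACG	Thr	2	4	0.06	0.12
GCT	Ala	61	53	1.80	1.59
GCC	Ala	0	7	0.00	0.21
GCA	Ala	14	20	0.41	0.60
GCG	Ala	5	4	0.15	0.12
TAT	Tyr	160	129	4.71	3.87
TAC	Tyr	14	24	0.41	0.72
TAA	*	0	0	0.00	0.00
TAG	*	0	0	0.00	0.00
CAT	His	46	45	1.36	1.35
CAC	His	0	2	0.00	0.06
CAA	Gln	30	30	0.88	0.90
CAG	Gln	8	26	0.24	0.78
AAT	Asn	146	99	4.30	2.97
AAC	Asn	8	5	0.24	0.15
AAA	Lys	85	67	2.50	2.01
AAG	Lys	14	33	0.41	0.99
GAT	Asp	60	55	1.77	1.65
GAC	Asp	6	5	0.18	0.15
GAA	Glu	48	54	1.41	1.62
GAG	Glu	26	35	0.77	1.05
TGT	Cys	33	41	0.97	1.23
TGC	Cys	1	0	0.03	0.00
TGA	Trp	50	59	1.47	1.77
TGG	Trp	12	28	0.35	0.84
CGT	Arg	25	16	0.74	0.48
CGC	Arg	0	1	0.00	0.03
CGA	Arg	3	13	0.09	0.39
CGG	Arg	3	3	0.09	0.09
AGT	Ser	89	86	2.62	2.58
AGC	Ser	4	5	0.12	0.15
AGA	Ser	103	95	3.03	2.85
AGG	Ser	20	35	0.59	1.05
GGT	Gly	77	101	2.27	3.03
GGC	Gly	3	8	0.09	0.24
GGA	Gly	51	58	1.50	1.74
GGG	Gly	24	31	0.71	0.93
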