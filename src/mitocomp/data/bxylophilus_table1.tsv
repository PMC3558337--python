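gene	class	start	end	strand	start_codon	stop_codon
cox1	PCG	1	1563	+	ATT	TAA
trnC	tRNA	1575	1628	+	.	.
trnM	tRNA	1634	1687	+	.	.
trnD	tRNA	1708	1762	+	.	.
trnG	tRNA	1766	1819	+	.	.
cox2	PCG	1820	2509	+	ATT	TAG
trnH	tRNA	2508	2562	+	.	.
rrnL	rRNA	2563	3510	+	.	.
nad3	PCG	3511	3840	+	ATT	TAA
nad5	PCG	3842	5410	+	ATT	TAA
trnA	tRNA	5410	5464	+	.	.
trnP	tRNA	5465	5521	+	.	.
trnV	tRNA	5522	5578	+	.	.
nad6	PCG	5579	6013	+	ATT	TAA
nad4L	PCG	6013	6246	+	ATA	TAA
trnW	tRNA	6247	6301	+	.	.
trnE	tRNA	6302	6356	+	.	.
rrnS	rRNA	6357	7056	+	.	.
trnS2	tRNA	7057	7111	+	.	.
trnY	tRNA	7112	7167	+	.	.
nad1	PCG	7168	8040	+	ATT	TAA
atp6	PCG	8036	8630	+	ATT	T
trnK	tRNA	8631	8690	+	.	.
trnL2	tRNA	8691	8745	+	.	.
trnS1	tRNA	8746	8798	+	.	.
nad2	PCG	8799	9623	+	ATT	TAA
trnI	tRNA	9635	9694	+	.	.
trnR	tRNA	9700	9752	+	.	.
trnQ	tRNA	9758	9811	+	.	.
trnF	tRNA	9812	9865	+	.	.
cob	PCG	9866	10967	+	ATA	T
trnL1	tRNA	10968	11022	+	.	.
cox3	PCG	11023	11790	+	ATT	TAA
trnN	tRNA	11791	11844	+	.	.
trnT	tRNA	11845	11898	+	.	.
nad4	PCG	11899	13128	+	ATA	TAA
NCR	NCR	13129	14778	+	.	.
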