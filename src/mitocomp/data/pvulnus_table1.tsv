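gene	class	start	end	strand	start_codon	stop_codon
cox1	PCG	1	1533	+	ATA	TAA
NCR1	NCR	1534	8380	+	.	.
trnH	tRNA	8381	8434	+	.	.
NCR2	NCR	8435	9335	+	.	.
trnL1	tRNA	9336	9393	+	.	.
rrnL	rRNA	9396	10290	+	.	.
nad3	PCG	10312	10641	+	ATT	TAG
cob	PCG	10651	11757	+	ATA	TAG
rrnS	rRNA	11881	12566	+	.	.
trnY	tRNA	12567	12620	+	.	.
trnW	tRNA	12621	12676	+	.	.
nad1	PCG	12677	13549	+	TTG	TAA
trnL2	tRNA	13551	13606	+	.	.
nad2	PCG	13608	14429	+	ATA	TAG
trnI	tRNA	14430	14485	+	.	.
cox3	PCG	14673	15449	+	ATA	TAG
trnN	tRNA	15450	15501	+	.	.
trnG	tRNA	15502	15557	+	.	.
trnK	tRNA	15559	15615	+	.	.
trnC	tRNA	15620	15673	+	.	.
trnF	tRNA	15674	15728	+	.	.
nad6	PCG	15729	16157	+	TTG	TAG
nad4L	PCG	16484	16714	+	ATT	TAG
cox2	PCG	16833	17513	+	ATA	TAG
nad4	PCG	17581	18792	+	ATA	TAA
trnD	tRNA	18802	18857	+	.	.
trnM	tRNA	18858	18911	+	.	.
trnT	tRNA	18954	19007	+	.	.
trnS1	tRNA	19053	19111	+	.	.
atp6	PCG	19123	19704	+	ATT	TAG
nad5	PCG	19780	21240	+	ATT	TAA
trnS2	tRNA	21241	21293	+	.	.
trnQ	tRNA	21304	21358	+	.	.
trnA	tRNA	21361	21416	+	.	.
trnP	tRNA	21424	21476	+	.	.
trnR	tRNA	21477	21530	+	.	.
trnV	tRNA	21531	21586	+	.	.
trnE	tRNA	21588	21645	+	.	.
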