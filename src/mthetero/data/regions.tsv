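name	class	start	end	strand
TF	tRNA	577	647	heavy
RNR1	rRNA	648	1601	heavy
TV	tRNA	1602	1670	heavy
RNR2	rRNA	1671	3229	heavy
TL1	tRNA	3230	3304	heavy
ND1	protein_coding	3307	4262	heavy
TI	tRNA	4263	4331	heavy
TQ	tRNA	4329	4400	light
TM	tRNA	4402	4469	heavy
ND2	protein_coding	4470	5511	heavy
TW	tRNA	5512	5579	heavy
TA	tRNA	5587	5655	light
TN	tRNA	5657	5729	light
TC	tRNA	5761	5826	light
TY	tRNA	5826	5891	light
CO1	protein_coding	5904	7445	heavy
TS1	tRNA	7446	7514	light
TD	tRNA	7518	7585	heavy
CO2	protein_coding	7586	8269	heavy
TK	tRNA	8295	8364	heavy
ATP8	protein_coding	8366	8572	heavy
ATP6	protein_coding	8527	9207	heavy
CO3	protein_coding	9207	9990	heavy
TG	tRNA	9991	10058	heavy
ND3	protein_coding	10059	10404	heavy
TR	tRNA	10405	10469	heavy
ND4L	protein_coding	10470	10766	heavy
ND4	protein_coding	10760	12137	heavy
TH	tRNA	12138	12206	heavy
TS2	tRNA	12207	12265	heavy
TL2	tRNA	12266	12336	heavy
ND5	protein_coding	12337	14148	heavy
ND6	protein_coding	14149	14673	light
TE	tRNA	14674	14742	light
CYB	protein_coding	14747	15887	heavy
TT	tRNA	15888	15953	heavy
TP	tRNA	15956	16023	light
control_region	control_region	16024	576	heavy
HV1	control_subregion	16024	16383	heavy
HV2	control_subregion	57	372	heavy
OHR	control_subregion	110	441	heavy
CSB1	control_subregion	213	235	heavy
CSB2	control_subregion	299	315	heavy
CSB3	control_subregion	346	363	heavy
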