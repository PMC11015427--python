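# organism: Phthorimaea absoluta (PA-KE)
# source: published mitogenome annotation; sequence deposited under BioProject PRJNA902348 (reference NC_050874)
# coordinates: 1-based inclusive, J-strand frame of reference
# terminal_igs: 3
name	category	strand	start	stop	start_codon	stop_codon
COI	PCG	J	1	1536	CGA	TAA
tRNA-Leu2	tRNA	J	1532	1599
COII	PCG	J	1600	2281	ATG	T
tRNA-Lys	tRNA	J	2282	2352
tRNA-Asp	tRNA	J	2361	2428
ATP8	PCG	J	2429	2599
ATP6	PCG	J	2593	3270	ATG	TAA
COIII	PCG	J	3271	4059	ATG	TAA
tRNA-Gly	tRNA	J	4062	4128
ND3	PCG	J	4129	4482	ATT	TAA
tRNA-Ala	tRNA	J	4552	4622
tRNA-Arg	tRNA	J	4623	4686
tRNA-Asn	tRNA	J	4689	4754
tRNA-Ser1	tRNA	J	4757	4822
tRNA-Glu	tRNA	J	4823	4888
tRNA-Phe	tRNA	N	4887	4952
ND5	PCG	N	4953	6687	ATA	T
tRNA-His	tRNA	N	6688	6753
ND4	PCG	N	6761	8101	CAT
ND4L	PCG	N	8103	8396	CAT
tRNA-Thr	tRNA	J	8399	8463
tRNA-Pro	tRNA	N	8464	8528
ND6	PCG	J	8531	9061	ATA	TAA
CYTB	PCG	J	9071	10219	ATG	TAA
tRNA-Ser2	tRNA	J	10227	10293
ND1	PCG	N	10316	11249	CAT
tRNA-Leu1	tRNA	N	11251	11318
16S-rRNA	rRNA	J	11319	12662
tRNA-Val	tRNA	N	12663	12728
12S-rRNA	rRNA	J	12729	13504
AT-rich	control-region	J	13505	13824
tRNA-Met	tRNA	J	13825	13893
tRNA-Ile	tRNA	J	13894	13958
tRNA-Gln	tRNA	N	13960	14028
ND2	PCG	J	14085	15098	ATT	TAA
tRNA-Trp	tRNA	J	15100	15164
tRNA-Cys	tRNA	N	15157	15222
tRNA-Tyr	tRNA	N	15227	15292
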