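# organism: Phthorimaea operculella (PO-KE)
# source: published mitogenome annotation; sequence deposited under BioProject PRJNA902348 (reference MW540822)
# coordinates: 1-based inclusive, J-strand frame of reference
# terminal_igs: 2
name	category	strand	start	stop	start_codon	stop_codon
COI	PCG	J	1	1536	CGA	TAA
tRNA-Leu2	tRNA	J	1532	1599
COII	PCG	J	1600	2281	ATG	T
tRNA-Lys	tRNA	J	2282	2352
tRNA-Asp	tRNA	J	2374	2443
ATP8	PCG	J	2444	2608
ATP6	PCG	J	2602	3279	ATC	TAA
COIII	PCG	J	3279	4067	ATG	TAA
tRNA-Gly	tRNA	J	4070	4136
ND3	PCG	J	4137	4490	ATT	TAA
tRNA-Ala	tRNA	J	4520	4586
tRNA-Arg	tRNA	J	4587	4652
tRNA-Asn	tRNA	J	4655	4720
tRNA-Ser1	tRNA	J	4721	4786
tRNA-Glu	tRNA	J	4791	4858
tRNA-Phe	tRNA	N	4865	4932
ND5	PCG	N	4933	6664	AAT	T
tRNA-His	tRNA	N	6665	6730
ND4	PCG	N	6739	8079	CAT
ND4L	PCG	N	8081	8368	AAT
tRNA-Thr	tRNA	J	8377	8440
tRNA-Pro	tRNA	N	8441	8505
ND6	PCG	J	8508	9038	ATA	TAA
CYTB	PCG	J	9046	10194	ATG	TAA
tRNA-Ser2	tRNA	J	10197	10263
ND1	PCG	N	10282	11220	CAT
tRNA-Leu1	tRNA	N	11222	11289
16S-rRNA	rRNA	J	11290	12630
tRNA-Val	tRNA	N	12631	12696
12S-rRNA	rRNA	J	12697	13504
AT-rich	control-region	J	13505	13792
tRNA-Met	tRNA	J	13793	13861
tRNA-Ile	tRNA	J	13862	13926
tRNA-Gln	tRNA	N	13929	13997
ND2	PCG	J	14055	15068	ATT	TAA
tRNA-Trp	tRNA	J	15070	15137
tRNA-Cys	tRNA	N	15130	15197
tRNA-Tyr	tRNA	N	15201	15267
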