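id	age_weeks	isotype	subclass	heavy_v	heavy_d	heavy_j	heavy_cdr3	heavy_cdr3_length	kappa_v	kappa_j	kappa_cdr3	kappa_cdr3_length
H2h4.1.6	28	IgG	IgG2b	3-3	1-1	4	ARGIFSYYYGSSYEGGYAMDY	21	5-45	5	QQSNSWPLT	9
H2h4.1.33	28	IgG	IgG2b	NS	NS	NS	NS	NS	4-59	2	YQWSSYPYT	9
H2h4.1.64	28	IgG	IgG2b	1-7	1-1	4	ARGGGNYVIRDYAMDY	16	12-44	5	QHHYGTPLT	9
H2h4.1.100	28	IgG	IgG2b	9-1	1-1	2	VDYYVSSYGY	10	5-45	5	QQSNSWPLT	9
H2h4.1.105	28	IgG	IgG2b	1-82	1-1	3	ARGGSSFFAY	10	6-15	4	QQFSTSPFT	9
H2h4.1.246	28	IgG	IgG2b	1-26	1-1	4	ARRGVTKGYYAMDY	14	6-15	1	QQYSSSPRT	9
H2h4.2.4	47	IgG	IgG2b	2-5	3-1	2	ARTRRSGFFDY	11	12-40	2	QHYYSTPYT	9
H2h4.2.23	47	IgG	IgG2b	10-3	6-3	4	VREAGLYAMDY	11	3-1	1	QQSRKVPWT	9
H2h4.2.26	47	IgG	IgG1	2-5	3-1	2	ARTRRSGFFDY	11	12-44	1	QHYYSTPPT	9
H2h4.2.33	47	IgG	IgG2b	2-9-1	1-1	4	ARNRGNLPHYYDLDY	15	6-20	5	GQSYSYPLT	9
H2h4.2.41	47	IgG	IgG1	5-4	1-3	4	ALGGGCAMDY	10	4-50	5	QQFTSSPSIT	10
H2h4.2.78	47	IgG	IgG1	5-6	4-1	2	ARPKTGAFDY	10	1-132	2	LQGTYYPHT	9
H2h4.7.8	66	IgG	IgG2b	1-4	1-1	2	ARSGGGDYGSSLCY	14	4-91	2	QHGSSLLRT	9
H2h4.7.21	66	IgG	IgG2c	5-6	2-4	1	ARQRTRLRRGVRGYFDV	17	12-46	5	QHYYSVLFT	9
H2h4.7.25	66	IgG	IgG2c	5-6	2-4	1	ARQRTRLRRGVRGYFDV	17	12-46	5	QHYYSVLFT	9
H2h4.7.41	66	IgG	IgG2c	1-9	2-12	2	AITHHFDY	8	9-129	4	LQYASFT	7
H2h4.7.50	66	IgG	IgG2b	1-4	1-1	2	ARSGGGDYGSSLCY	14	4-91	2	QHGSSLLRT	9
H2h4.7.79	66	IgG	IgG2b	1-85	3-1	2	ARRGSYYFDY	10	12-46	2	QHFYGTPYT	9
H2h4.7.90	66	IgG	IgG2b	1-53	2-3	2	ARWLLGDY	8	11-125	1	LQHSYLPWT	9
H2h4.7.94	66	IgG	IgG2b	1-4	1-1	2	ARSGGGDYGSSLCY	14	4-91	2	QHGSSLLRT	9
H2h4.7.97	66	IgG	IgG2c	2-2	1-1	4	ARVDPYLYGSSYNYAMDY	18	10-94	1	QQYSKLPWT	9
H2h4.7.107	66	IgG	IgG1	1-81	2-3	2	ARYQGYGDY	9	15-103	1	LQGQSYPWT	9
H2h4.7.117	66	IgG	IgG2b	1-53	2-2	4	ARVNGYLYAMDY	12	12-46	1	QHFWGTWT	8
H2h4.7.130	66	IgG	IgG2b	1-59	2-9	2	ARSPLLWLRRRYYFDY	16	12-44	5	QHHYGTPLT	9
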