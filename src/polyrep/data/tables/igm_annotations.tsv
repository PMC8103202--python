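id	age_weeks	isotype	subclass	heavy_v	heavy_d	heavy_j	heavy_cdr3	heavy_cdr3_length	kappa_v	kappa_j	kappa_cdr3	kappa_cdr3_length
H2h4.1.2	28	IgM		1-22	2-4	3	ARDDYDEAWFAY	12	3-10	2	QQNNEDPYT	9
H2h4.1.3	28	IgM		3-1	3-3	1	ARGDRWYFDV	10	10-94	2	QQYSKLYT	8
H2h4.1.4	28	IgM		14-2	1-1	4	ARDYGSSGYYYAMDY	15	13-85	2	QQYWGTPPT	9
H2h4.1.7	28	IgM		5-4	1-1	1	ARVLRYFDV	9	12-44	2	QHHYGTPYT	9
H2h4.1.14	28	IgM		14-3	2-10	2	ARSGYGNNDYFDY	13	4-74	5	QQYHSDPVT	9
H2h4.1.20	28	IgM		1-39	2-12	3	ARGPYYSESGGFAY	14	6-20	2	GQSYSYPYT	9
H2h4.1.22	28	IgM		1-43	3-1	2	ARYPRPV	7	3-4	2	QQSKEFPYT	9
H2h4.1.32	28	IgM		5-6	4-1	2	ARVFEANFYFDY	12	12-46	1	QHFYGTPWT	9
H2h4.1.44	28	IgM		5-2	4-1	2	AANWERLT	8	1-133	1	LQATHFPRT	9
H2h4.1.51	28	IgM		10-3	4-1	3	VGLSGTAY	8	5-45	4	QQSNSWPFT	9
H2h4.1.184	28	IgM		9-1	3-3	3	VKRGFAY	7	1-133	2	VQGTHFPYT	9
H2h4.1.185	28	IgM		5-6	1-1	2	ARHNYGSALFDY	12	3-10	1	QQNNEDPWT	9
H2h4.2.7	47	IgM		1-80	4-1	3	APNWAWFAY	9	1-122	2	LQVTHVPYT	9
H2h4.2.8	47	IgM		1-39	-	4	ARSSMDY	7	6-15	5	EQYSSYPLT	9
H2h4.2.22	47	IgM		1-5	1-1	2	ARVGEGY	7	2-109	5	AQMLERPLT	9
H2h4.2.40	47	IgM		1-64	2-13	2	AKGGSTRGDY	10	4-78	5	QQYSGYLT	8
H2h4.2.59	47	IgM		8-8	1-1	2	ARIGGSKNFDY	11	12-40	2	QHYYSTPYT	9
H2h4.2.62	47	IgM		2-2	4-1	2	ARKGPTGYYFDY	12	4-81	2	QQWSGYPYT	9
H2h4.2.63	47	IgM		2-2	4-1	2	ARKGPTGYYFDY	12	6-b	1	QQHYSSPWT	9
H2h4.2.100	47	IgM		1-43	2-1	2	ARSTMVTTYYFDY	13	1-110	1	FQGTHVPWT	9
H2h4.2.138	47	IgM		NS	NS	NS	NS	NS	10-96	1	QQDSKHPPT	9
H2h4.2.144	47	IgM		1-15	2-2	3	TRDYGFAYW	9	12-46	5	QHYYSTPLT	9
H2h4.2.162	47	IgM		1-69	2-5	4	ARRSNYDAMDY	11	1-133	2	VQGTHFPHT	9
H2h4.2.184	47	IgM		1-63	1-1	2	ARDGYYGSSYDY	12	2-109	1	AQMLERPRT	9
H2H4.7.3	66	IgM		1-26	3-3	2	ARSLYYFDY	9	NS	NS	NS	NS
H2H4.7.31	66	IgM		1-12	1-3	2	ARSRWNWYYFDY	12	19-93	5	LQYDNLPLT	9
H2H4.7.57	66	IgM		1-78	2-12	2	ARLRRRGS	8	4-57-1	1	QQGWDYPPT	9
H2H4.7.115	66	IgM		1-7	1-1	1	ARPSTVVDWYFDV	13	1-133	4	VQGTHFPFT	9
H2H4.7.118	66	IgM		1-55	3-2	2	AREAGDFDY	9	4-53	2	QQWSSYPYT	9
H2H4.7.123	66	IgM		NS	NS	NS	NS	NS	5-39	5	QNGHSFPLT	9
H2H4.7.126	66	IgM		1-19	4-1	1	AKTGTWYFDV	10	2-137	5	MQSLEYPLT	9
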