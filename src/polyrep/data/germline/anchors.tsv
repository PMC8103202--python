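locus	role	gene	anchor_start	fr1_end	cdr1_end	fr2_end	cdr2_end	fr3_end
heavy	V	1-22	285	75	99	150	174	288
heavy	V	1-26	285	75	99	150	174	288
heavy	V	1-39	285	75	99	150	174	288
heavy	V	1-4	285	75	99	150	174	288
heavy	V	1-43	285	75	99	150	174	288
heavy	V	1-7	285	75	99	150	174	288
heavy	V	10-3	285	75	99	150	174	288
heavy	V	14-2	285	75	99	150	174	288
heavy	V	2-2	285	75	99	150	174	288
heavy	V	2-5	285	75	99	150	174	288
heavy	V	3-1	285	75	99	150	174	288
heavy	V	3-3	285	75	99	150	174	288
heavy	V	5-4	285	75	99	150	174	288
heavy	V	5-6	285	75	99	150	174	288
heavy	V	9-1	285	75	99	150	174	288
kappa	V	10-94	258	69	99	144	165	261
kappa	V	12-44	258	69	99	144	165	261
kappa	V	12-46	258	69	99	144	165	261
kappa	V	13-85	258	69	99	144	165	261
kappa	V	3-10	258	69	99	144	165	261
kappa	V	3-4	258	69	99	144	165	261
kappa	V	4-74	258	69	99	144	165	261
kappa	V	4-91	258	69	99	144	165	261
kappa	V	5-45	258	69	99	144	165	261
kappa	V	6-20	258	69	99	144	165	261
heavy	D	1-1						
heavy	D	2-12						
heavy	D	2-4						
heavy	D	3-3						
heavy	D	4-1						
heavy	J	1	12					
heavy	J	2	12					
heavy	J	3	12					
heavy	J	4	18					
kappa	J	1	6					
kappa	J	2	6					
kappa	J	3	6					
kappa	J	4	6					
kappa	J	5	6					
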