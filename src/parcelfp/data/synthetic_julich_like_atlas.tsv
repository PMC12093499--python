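parcel_id	parcel_name	hemisphere	macro_region	is_insular_seed	granularity
Ia1_l	Ia1	L	insular	1	agranular
Ia2_l	Ia2	L	insular	1	agranular
Ia3_l	Ia3	L	insular	1	agranular
Id1_l	Id1	L	insular	1	dysgranular
Id2_l	Id2	L	insular	1	dysgranular
Id3_l	Id3	L	insular	1	dysgranular
Id4_l	Id4	L	insular	1	dysgranular
Id5_l	Id5	L	insular	1	dysgranular
Id6_l	Id6	L	insular	1	dysgranular
Id7_l	Id7	L	insular	1	dysgranular
Id8_l	Id8	L	insular	1	dysgranular
Id9_l	Id9	L	insular	1	dysgranular
Id10_l	Id10	L	insular	1	dysgranular
Ig1_l	Ig1	L	insular	1	granular
Ig2_l	Ig2	L	insular	1	granular
Ig3_l	Ig3	L	insular	1	granular
Frontal_to_Temporal_I_l	Frontal_to_Temporal_I	L	frontal	0	
Frontal_to_Temporal_II_l	Frontal_to_Temporal_II	L	frontal	0	
Frontal_I_l	Frontal_I	L	frontal	0	
Frontal_II_l	Frontal_II	L	frontal	0	
IFS1_l	IFS1	L	frontal	0	
IFS2_l	IFS2	L	frontal	0	
IF3_l	IF3	L	frontal	0	
IFS4_l	IFS4	L	frontal	0	
IFJ1_l	IFJ1	L	frontal	0	
IFJ2_l	IFJ2	L	frontal	0	
8v1_l	8v1	L	frontal	0	
8v2_l	8v2	L	frontal	0	
Fp1_l	Fp1	L	frontal	0	
Fp2_l	Fp2	L	frontal	0	
8d1_l	8d1	L	frontal	0	
8d2_l	8d2	L	frontal	0	
OP5_l	OP5	L	frontal	0	
OP6_l	OP6	L	frontal	0	
OP7_l	OP7	L	frontal	0	
OP8_l	OP8	L	frontal	0	
OP9_l	OP9	L	frontal	0	
44_l	44	L	frontal	0	
45_l	45	L	frontal	0	
Fo1_l	Fo1	L	frontal	0	
Fo2_l	Fo2	L	frontal	0	
Fo3_l	Fo3	L	frontal	0	
Fo4_l	Fo4	L	frontal	0	
Fo5_l	Fo5	L	frontal	0	
Fo6_l	Fo6	L	frontal	0	
Fo7_l	Fo7	L	frontal	0	
6d1_l	6d1	L	frontal	0	
6d2_l	6d2	L	frontal	0	
6ma_l	6ma	L	frontal	0	
6d3_l	6d3	L	frontal	0	
6mp_l	6mp	L	frontal	0	
4p_l	4p	L	frontal	0	
4a_l	4a	L	frontal	0	
TE1.0_l	TE1.0	L	temporal	0	
TE1.1_l	TE1.1	L	temporal	0	
TE1.2_l	TE1.2	L	temporal	0	
TE2.1_l	TE2.1	L	temporal	0	
TE2.2_l	TE2.2	L	temporal	0	
TE3_l	TE3	L	temporal	0	
TI_l	TI	L	temporal	0	
STS1_l	STS1	L	temporal	0	
STS2_l	STS2	L	temporal	0	
FG1_l	FG1	L	temporal	0	
FG2_l	FG2	L	temporal	0	
FG3_l	FG3	L	temporal	0	
FG4_l	FG4	L	temporal	0	
hOc1_l	hOc1	L	occipital	0	
hOc2_l	hOc2	L	occipital	0	
hOc3v_l	hOc3v	L	occipital	0	
hOc3d_l	hOc3d	L	occipital	0	
hOc4v_l	hOc4v	L	occipital	0	
hOc4d_l	hOc4d	L	occipital	0	
hOc4lp_l	hOc4lp	L	occipital	0	
hOc4Ia_l	hOc4Ia	L	occipital	0	
hOc5_l	hOc5	L	occipital	0	
hOc6_l	hOc6	L	occipital	0	
1_l	1	L	parietal	0	
2_l	2	L	parietal	0	
3a_l	3a	L	parietal	0	
3b_l	3b	L	parietal	0	
OP1_l	OP1	L	parietal	0	
OP2_l	OP2	L	parietal	0	
OP3_l	OP3	L	parietal	0	
OP4_l	OP4	L	parietal	0	
5Ci_l	5Ci	L	parietal	0	
5L_l	5L	L	parietal	0	
5M_l	5M	L	parietal	0	
7A_l	7A	L	parietal	0	
7PC_l	7PC	L	parietal	0	
7M_l	7M	L	parietal	0	
7P_l	7P	L	parietal	0	
PF_l	PF	L	parietal	0	
PFm_l	PFm	L	parietal	0	
PFt_l	PFt	L	parietal	0	
PFop_l	PFop	L	parietal	0	
PFcm_l	PFcm	L	parietal	0	
PGa_l	PGa	L	parietal	0	
PGp_l	PGp	L	parietal	0	
hIP1_l	hIP1	L	parietal	0	
hIP2_l	hIP2	L	parietal	0	
25_l	25	L	limbic	0	
33_l	33	L	limbic	0	
s24_l	s24	L	limbic	0	
s32_l	s32	L	limbic	0	
p24_l	p24	L	limbic	0	
p32_l	p32	L	limbic	0	
Ent_l	Ent	L	limbic	0	
Ia1_r	Ia1	R	insular	1	agranular
Ia2_r	Ia2	R	insular	1	agranular
Ia3_r	Ia3	R	insular	1	agranular
Id1_r	Id1	R	insular	1	dysgranular
Id2_r	Id2	R	insular	1	dysgranular
Id3_r	Id3	R	insular	1	dysgranular
Id4_r	Id4	R	insular	1	dysgranular
Id5_r	Id5	R	insular	1	dysgranular
Id6_r	Id6	R	insular	1	dysgranular
Id7_r	Id7	R	insular	1	dysgranular
Id8_r	Id8	R	insular	1	dysgranular
Id9_r	Id9	R	insular	1	dysgranular
Id10_r	Id10	R	insular	1	dysgranular
Ig1_r	Ig1	R	insular	1	granular
Ig2_r	Ig2	R	insular	1	granular
Ig3_r	Ig3	R	insular	1	granular
Frontal_to_Temporal_I_r	Frontal_to_Temporal_I	R	frontal	0	
Frontal_to_Temporal_II_r	Frontal_to_Temporal_II	R	frontal	0	
Frontal_I_r	Frontal_I	R	frontal	0	
Frontal_II_r	Frontal_II	R	frontal	0	
IFS1_r	IFS1	R	frontal	0	
IFS2_r	IFS2	R	frontal	0	
IF3_r	IF3	R	frontal	0	
IFS4_r	IFS4	R	frontal	0	
IFJ1_r	IFJ1	R	frontal	0	
IFJ2_r	IFJ2	R	frontal	0	
8v1_r	8v1	R	frontal	0	
8v2_r	8v2	R	frontal	0	
Fp1_r	Fp1	R	frontal	0	
Fp2_r	Fp2	R	frontal	0	
8d1_r	8d1	R	frontal	0	
8d2_r	8d2	R	frontal	0	
OP5_r	OP5	R	frontal	0	
OP6_r	OP6	R	frontal	0	
OP7_r	OP7	R	frontal	0	
OP8_r	OP8	R	frontal	0	
OP9_r	OP9	R	frontal	0	
44_r	44	R	frontal	0	
45_r	45	R	frontal	0	
Fo1_r	Fo1	R	frontal	0	
Fo2_r	Fo2	R	frontal	0	
Fo3_r	Fo3	R	frontal	0	
Fo4_r	Fo4	R	frontal	0	
Fo5_r	Fo5	R	frontal	0	
Fo6_r	Fo6	R	frontal	0	
Fo7_r	Fo7	R	frontal	0	
6d1_r	6d1	R	frontal	0	
6d2_r	6d2	R	frontal	0	
6ma_r	6ma	R	frontal	0	
6d3_r	6d3	R	frontal	0	
6mp_r	6mp	R	frontal	0	
4p_r	4p	R	frontal	0	
4a_r	4a	R	frontal	0	
TE1.0_r	TE1.0	R	temporal	0	
TE1.1_r	TE1.1	R	temporal	0	
TE1.2_r	TE1.2	R	temporal	0	
TE2.1_r	TE2.1	R	temporal	0	
TE2.2_r	TE2.2	R	temporal	0	
TE3_r	TE3	R	temporal	0	
TI_r	TI	R	temporal	0	
STS1_r	STS1	R	temporal	0	
STS2_r	STS2	R	temporal	0	
FG1_r	FG1	R	temporal	0	
FG2_r	FG2	R	temporal	0	
FG3_r	FG3	R	temporal	0	
FG4_r	FG4	R	temporal	0	
hOc1_r	hOc1	R	occipital	0	
hOc2_r	hOc2	R	occipital	0	
hOc3v_r	hOc3v	R	occipital	0	
hOc3d_r	hOc3d	R	occipital	0	
hOc4v_r	hOc4v	R	occipital	0	
hOc4d_r	hOc4d	R	occipital	0	
hOc4lp_r	hOc4lp	R	occipital	0	
hOc4Ia_r	hOc4Ia	R	occipital	0	
hOc5_r	hOc5	R	occipital	0	
hOc6_r	hOc6	R	occipital	0	
1_r	1	R	parietal	0	
2_r	2	R	parietal	0	
3a_r	3a	R	parietal	0	
3b_r	3b	R	parietal	0	
OP1_r	OP1	R	parietal	0	
OP2_r	OP2	R	parietal	0	
OP3_r	OP3	R	parietal	0	
OP4_r	OP4	R	parietal	0	
5Ci_r	5Ci	R	parietal	0	
5L_r	5L	R	parietal	0	
5M_r	5M	R	parietal	0	
7A_r	7A	R	parietal	0	
7PC_r	7PC	R	parietal	0	
7M_r	7M	R	parietal	0	
7P_r	7P	R	parietal	0	
PF_r	PF	R	parietal	0	
PFm_r	PFm	R	parietal	0	
PFt_r	PFt	R	parietal	0	
PFop_r	PFop	R	parietal	0	
PFcm_r	PFcm	R	parietal	0	
PGa_r	PGa	R	parietal	0	
PGp_r	PGp	R	parietal	0	
hIP1_r	hIP1	R	parietal	0	
hIP2_r	hIP2	R	parietal	0	
25_r	25	R	limbic	0	
33_r	33	R	limbic	0	
s24_r	s24	R	limbic	0	
s32_r	s32	R	limbic	0	
p24_r	p24	R	limbic	0	
p32_r	p32	R	limbic	0	
Ent_r	Ent	R	limbic	0	
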