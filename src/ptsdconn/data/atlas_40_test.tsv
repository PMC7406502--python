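node_id	node_name	network	hemisphere
1	ctx_L_001	default_mode	L
2	ctx_R_002	default_mode	R
3	ctx_L_003	default_mode	L
4	ctx_R_004	default_mode	R
5	ctx_L_005	default_mode	L
6	ctx_R_006	frontoparietal	R
7	ctx_L_007	frontoparietal	L
8	ctx_R_008	frontoparietal	R
9	ctx_L_009	frontoparietal	L
10	ctx_R_010	frontoparietal	R
11	ctx_L_011	cingulo_opercular	L
12	ctx_R_012	cingulo_opercular	R
13	ctx_L_013	cingulo_opercular	L
14	ctx_R_014	cingulo_opercular	R
15	ctx_L_015	cingulo_opercular	L
16	ctx_R_016	salience	R
17	ctx_L_017	salience	L
18	ctx_R_018	salience	R
19	ctx_L_019	salience	L
20	ctx_R_020	salience	R
21	ctx_L_021	dorsal_attention	L
22	ctx_R_022	dorsal_attention	R
23	ctx_L_023	dorsal_attention	L
24	ctx_R_024	dorsal_attention	R
25	ctx_L_025	dorsal_attention	L
26	ctx_R_026	ventral_attention	R
27	ctx_L_027	ventral_attention	L
28	ctx_R_028	ventral_attention	R
29	ctx_L_029	ventral_attention	L
30	ctx_R_030	ventral_attention	R
31	ctx_L_031	auditory	L
32	ctx_R_032	auditory	R
33	ctx_L_033	auditory	L
34	ctx_R_034	auditory	R
35	ctx_L_035	auditory	L
36	ctx_R_036	visual	R
37	ctx_L_037	visual	L
38	ctx_R_038	visual	R
39	ctx_L_039	visual	L
40	ctx_R_040	visual	R
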