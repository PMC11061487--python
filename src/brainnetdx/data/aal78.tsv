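index	aal_name	display_name	hemisphere	lobe	aal_label
0	Precentral_L	L_Precentral gyrus	L	frontal	2001
1	Precentral_R	R_Precentral gyrus	R	frontal	2002
2	Frontal_Sup_L	L_Superior frontal gyrus (dorsolateral)	L	frontal	2101
3	Frontal_Sup_R	R_Superior frontal gyrus (dorsolateral)	R	frontal	2102
4	Frontal_Sup_Orb_L	L_Orbitofrontal cortex (superior)	L	frontal	2111
5	Frontal_Sup_Orb_R	R_Orbitofrontal cortex (superior)	R	frontal	2112
6	Frontal_Mid_L	L_Middle frontal gyrus	L	frontal	2201
7	Frontal_Mid_R	R_Middle frontal gyrus	R	frontal	2202
8	Frontal_Mid_Orb_L	L_Orbitofrontal cortex (middle)	L	frontal	2211
9	Frontal_Mid_Orb_R	R_Orbitofrontal cortex (middle)	R	frontal	2212
10	Frontal_Inf_Oper_L	L_Inferior frontal gyrus (opercular)	L	frontal	2301
11	Frontal_Inf_Oper_R	R_Inferior frontal gyrus (opercular)	R	frontal	2302
12	Frontal_Inf_Tri_L	L_Inferior frontal gyrus (triangular)	L	frontal	2311
13	Frontal_Inf_Tri_R	R_Inferior frontal gyrus (triangular)	R	frontal	2312
14	Frontal_Inf_Orb_L	L_Orbitofrontal cortex (inferior)	L	frontal	2321
15	Frontal_Inf_Orb_R	R_Orbitofrontal cortex (inferior)	R	frontal	2322
16	Rolandic_Oper_L	L_Rolandic operculum	L	frontal	2331
17	Rolandic_Oper_R	R_Rolandic operculum	R	frontal	2332
18	Supp_Motor_Area_L	L_Supplementary motor area	L	frontal	2401
19	Supp_Motor_Area_R	R_Supplementary motor area	R	frontal	2402
20	Olfactory_L	L_Olfactory cortex	L	limbic	2501
21	Olfactory_R	R_Olfactory cortex	R	limbic	2502
22	Frontal_Sup_Medial_L	L_Superior frontal gyrus (medial)	L	frontal	2601
23	Frontal_Sup_Medial_R	R_Superior frontal gyrus (medial)	R	frontal	2602
24	Frontal_Med_Orb_L	L_Orbitofrontal cortex (medial)	L	frontal	2611
25	Frontal_Med_Orb_R	R_Orbitofrontal cortex (medial)	R	frontal	2612
26	Rectus_L	L_Gyrus rectus	L	frontal	2701
27	Rectus_R	R_Gyrus rectus	R	frontal	2702
28	Insula_L	L_Insula	L	insula	3001
29	Insula_R	R_Insula	R	insula	3002
30	Cingulum_Ant_L	L_Anterior cingulate gyrus	L	limbic	4001
31	Cingulum_Ant_R	R_Anterior cingulate gyrus	R	limbic	4002
32	Cingulum_Mid_L	L_Middle cingulate gyrus	L	limbic	4011
33	Cingulum_Mid_R	R_Middle cingulate gyrus	R	limbic	4012
34	Cingulum_Post_L	L_Posterior cingulate gyrus	L	limbic	4021
35	Cingulum_Post_R	R_Posterior cingulate gyrus	R	limbic	4022
36	ParaHippocampal_L	L_Parahippocampal gyrus	L	limbic	4111
37	ParaHippocampal_R	R_Parahippocampal gyrus	R	limbic	4112
38	Calcarine_L	L_Calcarine cortex	L	occipital	5001
39	Calcarine_R	R_Calcarine cortex	R	occipital	5002
40	Cuneus_L	L_Cuneus	L	occipital	5011
41	Cuneus_R	R_Cuneus	R	occipital	5012
42	Lingual_L	L_Lingual gyrus	L	occipital	5021
43	Lingual_R	R_Lingual gyrus	R	occipital	5022
44	Occipital_Sup_L	L_Superior occipital gyrus	L	occipital	5101
45	Occipital_Sup_R	R_Superior occipital gyrus	R	occipital	5102
46	Occipital_Mid_L	L_Middle occipital gyrus	L	occipital	5201
47	Occipital_Mid_R	R_Middle occipital gyrus	R	occipital	5202
48	Occipital_Inf_L	L_Inferior occipital gyrus	L	occipital	5301
49	Occipital_Inf_R	R_Inferior occipital gyrus	R	occipital	5302
50	Fusiform_L	L_Fusiform gyrus	L	occipital	5401
51	Fusiform_R	R_Fusiform gyrus	R	occipital	5402
52	Postcentral_L	L_Postcentral gyrus	L	parietal	6001
53	Postcentral_R	R_Postcentral gyrus	R	parietal	6002
54	Parietal_Sup_L	L_Superior parietal gyrus	L	parietal	6101
55	Parietal_Sup_R	R_Superior parietal gyrus	R	parietal	6102
56	Parietal_Inf_L	L_Inferior parietal lobule	L	parietal	6201
57	Parietal_Inf_R	R_Inferior parietal lobule	R	parietal	6202
58	SupraMarginal_L	L_Supramarginal gyrus	L	parietal	6211
59	SupraMarginal_R	R_Supramarginal gyrus	R	parietal	6212
60	Angular_L	L_Angular gyrus	L	parietal	6221
61	Angular_R	R_Angular gyrus	R	parietal	6222
62	Precuneus_L	L_Precuneus	L	parietal	6301
63	Precuneus_R	R_Precuneus	R	parietal	6302
64	Paracentral_Lobule_L	L_Paracentral lobule	L	frontal	6401
65	Paracentral_Lobule_R	R_Paracentral lobule	R	frontal	6402
66	Heschl_L	L_Heschl gyrus	L	temporal	8101
67	Heschl_R	R_Heschl gyrus	R	temporal	8102
68	Temporal_Sup_L	L_Superior temporal gyrus	L	temporal	8111
69	Temporal_Sup_R	R_Superior temporal gyrus	R	temporal	8112
70	Temporal_Pole_Sup_L	L_Temporal pole (superior)	L	temporal	8121
71	Temporal_Pole_Sup_R	R_Temporal pole (superior)	R	temporal	8122
72	Temporal_Mid_L	L_Middle temporal gyrus	L	temporal	8201
73	Temporal_Mid_R	R_Middle temporal gyrus	R	temporal	8202
74	Temporal_Pole_Mid_L	L_Temporal pole (middle)	L	temporal	8211
75	Temporal_Pole_Mid_R	R_Temporal pole (middle)	R	temporal	8212
76	Temporal_Inf_L	L_Inferior temporal gyrus	L	temporal	8301
77	Temporal_Inf_R	R_Inferior temporal gyrus	R	temporal	8302
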