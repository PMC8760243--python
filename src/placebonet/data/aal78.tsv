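index	region	hemisphere	cortical
1	Precentral_L	L	1
2	Precentral_R	R	1
3	Frontal_Sup_L	L	1
4	Frontal_Sup_R	R	1
5	Frontal_Sup_Orb_L	L	1
6	Frontal_Sup_Orb_R	R	1
7	Frontal_Mid_L	L	1
8	Frontal_Mid_R	R	1
9	Frontal_Mid_Orb_L	L	1
10	Frontal_Mid_Orb_R	R	1
11	Frontal_Inf_Oper_L	L	1
12	Frontal_Inf_Oper_R	R	1
13	Frontal_Inf_Tri_L	L	1
14	Frontal_Inf_Tri_R	R	1
15	Frontal_Inf_Orb_L	L	1
16	Frontal_Inf_Orb_R	R	1
17	Rolandic_Oper_L	L	1
18	Rolandic_Oper_R	R	1
19	Supp_Motor_Area_L	L	1
20	Supp_Motor_Area_R	R	1
21	Olfactory_L	L	1
22	Olfactory_R	R	1
23	Frontal_Sup_Medial_L	L	1
24	Frontal_Sup_Medial_R	R	1
25	Frontal_Med_Orb_L	L	1
26	Frontal_Med_Orb_R	R	1
27	Rectus_L	L	1
28	Rectus_R	R	1
29	Insula_L	L	1
30	Insula_R	R	1
31	Cingulum_Ant_L	L	1
32	Cingulum_Ant_R	R	1
33	Cingulum_Mid_L	L	1
34	Cingulum_Mid_R	R	1
35	Cingulum_Post_L	L	1
36	Cingulum_Post_R	R	1
37	ParaHippocampal_L	L	1
38	ParaHippocampal_R	R	1
39	Calcarine_L	L	1
40	Calcarine_R	R	1
41	Cuneus_L	L	1
42	Cuneus_R	R	1
43	Lingual_L	L	1
44	Lingual_R	R	1
45	Occipital_Sup_L	L	1
46	Occipital_Sup_R	R	1
47	Occipital_Mid_L	L	1
48	Occipital_Mid_R	R	1
49	Occipital_Inf_L	L	1
50	Occipital_Inf_R	R	1
51	Fusiform_L	L	1
52	Fusiform_R	R	1
53	Postcentral_L	L	1
54	Postcentral_R	R	1
55	Parietal_Sup_L	L	1
56	Parietal_Sup_R	R	1
57	Parietal_Inf_L	L	1
58	Parietal_Inf_R	R	1
59	SupraMarginal_L	L	1
60	SupraMarginal_R	R	1
61	Angular_L	L	1
62	Angular_R	R	1
63	Precuneus_L	L	1
64	Precuneus_R	R	1
65	Paracentral_Lobule_L	L	1
66	Paracentral_Lobule_R	R	1
67	Heschl_L	L	1
68	Heschl_R	R	1
69	Temporal_Sup_L	L	1
70	Temporal_Sup_R	R	1
71	Temporal_Pole_Sup_L	L	1
72	Temporal_Pole_Sup_R	R	1
73	Temporal_Mid_L	L	1
74	Temporal_Mid_R	R	1
75	Temporal_Pole_Mid_L	L	1
76	Temporal_Pole_Mid_R	R	1
77	Temporal_Inf_L	L	1
78	Temporal_Inf_R	R	1
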