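index	name	system
1	Precentral_L	cortical
2	Precentral_R	cortical
3	Frontal_Sup_L	cortical
4	Frontal_Sup_R	cortical
5	Frontal_Sup_Orb_L	cortical
6	Frontal_Sup_Orb_R	cortical
7	Frontal_Mid_L	cortical
8	Frontal_Mid_R	cortical
9	Frontal_Mid_Orb_L	cortical
10	Frontal_Mid_Orb_R	cortical
11	Frontal_Inf_Oper_L	cortical
12	Frontal_Inf_Oper_R	cortical
13	Frontal_Inf_Tri_L	cortical
14	Frontal_Inf_Tri_R	cortical
15	Frontal_Inf_Orb_L	cortical
16	Frontal_Inf_Orb_R	cortical
17	Rolandic_Oper_L	cortical
18	Rolandic_Oper_R	cortical
19	Supp_Motor_Area_L	cortical
20	Supp_Motor_Area_R	cortical
21	Olfactory_L	cortical
22	Olfactory_R	cortical
23	Frontal_Sup_Medial_L	cortical
24	Frontal_Sup_Medial_R	cortical
25	Frontal_Med_Orb_L	cortical
26	Frontal_Med_Orb_R	cortical
27	Rectus_L	cortical
28	Rectus_R	cortical
29	Insula_L	cortical
30	Insula_R	cortical
31	Cingulum_Ant_L	cortical
32	Cingulum_Ant_R	cortical
33	Cingulum_Mid_L	cortical
34	Cingulum_Mid_R	cortical
35	Cingulum_Post_L	cortical
36	Cingulum_Post_R	cortical
37	Hippocampus_L	cortical
38	Hippocampus_R	cortical
39	ParaHippocampal_L	cortical
40	ParaHippocampal_R	cortical
41	Calcarine_L	cortical
42	Calcarine_R	cortical
43	Cuneus_L	cortical
44	Cuneus_R	cortical
45	Lingual_L	cortical
46	Lingual_R	cortical
47	Occipital_Sup_L	cortical
48	Occipital_Sup_R	cortical
49	Occipital_Mid_L	cortical
50	Occipital_Mid_R	cortical
51	Occipital_Inf_L	cortical
52	Occipital_Inf_R	cortical
53	Fusiform_L	cortical
54	Fusiform_R	cortical
55	Postcentral_L	cortical
56	Postcentral_R	cortical
57	Parietal_Sup_L	cortical
58	Parietal_Sup_R	cortical
59	Parietal_Inf_L	cortical
60	Parietal_Inf_R	cortical
61	SupraMarginal_L	cortical
62	SupraMarginal_R	cortical
63	Angular_L	cortical
64	Angular_R	cortical
65	Precuneus_L	cortical
66	Precuneus_R	cortical
67	Paracentral_Lobule_L	cortical
68	Paracentral_Lobule_R	cortical
69	Heschl_L	cortical
70	Heschl_R	cortical
71	Temporal_Sup_L	cortical
72	Temporal_Sup_R	cortical
73	Temporal_Pole_Sup_L	cortical
74	Temporal_Pole_Sup_R	cortical
75	Temporal_Mid_L	cortical
76	Temporal_Mid_R	cortical
77	Temporal_Pole_Mid_L	cortical
78	Temporal_Pole_Mid_R	cortical
79	Temporal_Inf_L	cortical
80	Temporal_Inf_R	cortical
81	Caudate_L	subcortical
82	Caudate_R	subcortical
83	Putamen_L	subcortical
84	Putamen_R	subcortical
85	Globus_Pallidus_Ext_L	subcortical
86	Globus_Pallidus_Ext_R	subcortical
87	Globus_Pallidus_Int_L	subcortical
88	Globus_Pallidus_Int_R	subcortical
89	Thalamus_L	subcortical
90	Thalamus_R	subcortical
91	Subthalamic_Nucleus_L	subcortical
92	Subthalamic_Nucleus_R	subcortical
93	Substantia_Nigra_L	subcortical
94	Substantia_Nigra_R	subcortical
95	Red_Nucleus_L	subcortical
96	Red_Nucleus_R	subcortical
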