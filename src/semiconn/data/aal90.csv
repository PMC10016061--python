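index,name,hemisphere
1,Precentral_L,L
2,Precentral_R,R
3,Frontal_Sup_L,L
4,Frontal_Sup_R,R
5,Frontal_Sup_Orb_L,L
6,Frontal_Sup_Orb_R,R
7,Frontal_Mid_L,L
8,Frontal_Mid_R,R
9,Frontal_Mid_Orb_L,L
10,Frontal_Mid_Orb_R,R
11,Frontal_Inf_Oper_L,L
12,Frontal_Inf_Oper_R,R
13,Frontal_Inf_Tri_L,L
14,Frontal_Inf_Tri_R,R
15,Frontal_Inf_Orb_L,L
16,Frontal_Inf_Orb_R,R
17,Rolandic_Oper_L,L
18,Rolandic_Oper_R,R
19,Supp_Motor_Area_L,L
20,Supp_Motor_Area_R,R
21,Olfactory_L,L
22,Olfactory_R,R
23,Frontal_Sup_Medial_L,L
24,Frontal_Sup_Medial_R,R
25,Frontal_Med_Orb_L,L
26,Frontal_Med_Orb_R,R
27,Rectus_L,L
28,Rectus_R,R
29,Insula_L,L
30,Insula_R,R
31,Cingulum_Ant_L,L
32,Cingulum_Ant_R,R
33,Cingulum_Mid_L,L
34,Cingulum_Mid_R,R
35,Cingulum_Post_L,L
36,Cingulum_Post_R,R
37,Hippocampus_L,L
38,Hippocampus_R,R
39,ParaHippocampal_L,L
40,ParaHippocampal_R,R
41,Amygdala_L,L
42,Amygdala_R,R
43,Calcarine_L,L
44,Calcarine_R,R
45,Cuneus_L,L
46,Cuneus_R,R
47,Lingual_L,L
48,Lingual_R,R
49,Occipital_Sup_L,L
50,Occipital_Sup_R,R
51,Occipital_Mid_L,L
52,Occipital_Mid_R,R
53,Occipital_Inf_L,L
54,Occipital_Inf_R,R
55,Fusiform_L,L
56,Fusiform_R,R
57,Postcentral_L,L
58,Postcentral_R,R
59,Parietal_Sup_L,L
60,Parietal_Sup_R,R
61,Parietal_Inf_L,L
62,Parietal_Inf_R,R
63,SupraMarginal_L,L
64,SupraMarginal_R,R
65,Angular_L,L
66,Angular_R,R
67,Precuneus_L,L
68,Precuneus_R,R
69,Paracentral_Lobule_L,L
70,Paracentral_Lobule_R,R
71,Caudate_L,L
72,Caudate_R,R
73,Putamen_L,L
74,Putamen_R,R
75,Pallidum_L,L
76,Pallidum_R,R
77,Thalamus_L,L
78,Thalamus_R,R
79,Heschl_L,L
80,Heschl_R,R
81,Temporal_Sup_L,L
82,Temporal_Sup_R,R
83,Temporal_Pole_Sup_L,L
84,Temporal_Pole_Sup_R,R
85,Temporal_Mid_L,L
86,Temporal_Mid_R,R
87,Temporal_Pole_Mid_L,L
88,Temporal_Pole_Mid_R,R
89,Temporal_Inf_L,L
90,Temporal_Inf_R,R
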