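label_id	name	abbreviation
1	Superior frontal gyrus, dorsolateral (left)	SFGdor_L
2	Superior frontal gyrus, dorsolateral (right)	SFGdor_R
3	Middle frontal gyrus (left)	MFG_L
4	Middle frontal gyrus (right)	MFG_R
5	Inferior frontal gyrus, opercular part (left)	IFGoperc_L
6	Inferior frontal gyrus, opercular part (right)	IFGoperc_R
7	Inferior frontal gyrus, triangular part (left)	IFGtriang_L
8	Inferior frontal gyrus, triangular part (right)	IFGtriang_R
9	Rolandic operculum (left)	ROL_L
10	Rolandic operculum (right)	ROL_R
11	Supplementary motor area (left)	SMA_L
12	Supplementary motor area (right)	SMA_R
13	Superior frontal gyrus, medial (left)	SFGmed_L
14	Superior frontal gyrus, medial (right)	SFGmed_R
15	Cuneus (left)	CUN_L
16	Cuneus (right)	CUN_R
17	Lingual gyrus (left)	LING_L
18	Lingual gyrus (right)	LING_R
19	Superior occipital gyrus (left)	SOG_L
20	Superior occipital gyrus (right)	SOG_R
21	Middle occipital gyrus (left)	MOG_L
22	Middle occipital gyrus (right)	MOG_R
23	Inferior occipital gyrus (left)	IOG_L
24	Inferior occipital gyrus (right)	IOG_R
25	Fusiform gyrus (left)	FFG_L
26	Fusiform gyrus (right)	FFG_R
27	Superior parietal gyrus (left)	SPG_L
28	Superior parietal gyrus (right)	SPG_R
29	Inferior parietal, but supramarginal and angular gyri (left)	IPL_L
30	Inferior parietal, but supramarginal and angular gyri (right)	IPL_R
31	Supramarginal gyrus (left)	SMG_L
32	Supramarginal gyrus (right)	SMG_R
33	Angular gyrus (left)	ANG_L
34	Angular gyrus (right)	ANG_R
35	Precuneus (left)	PCUN_L
36	Precuneus (right)	PCUN_R
37	Paracentral lobule (left)	PCL_L
38	Paracentral lobule (right)	PCL_R
39	Superior temporal gyrus (left)	STG_L
40	Superior temporal gyrus (right)	STG_R
41	Middle temporal gyrus (left)	MTG_L
42	Middle temporal gyrus (right)	MTG_R
43	Inferior temporal gyrus (left)	ITG_L
44	Inferior temporal gyrus (right)	ITG_R
45	Superior frontal gyrus, orbital part (left)	ORBsup_L
46	Superior frontal gyrus, orbital part (right)	ORBsup_R
47	Middle frontal gyrus, orbital part (left)	ORBmid_L
48	Middle frontal gyrus, orbital part (right)	ORBmid_R
49	Inferior frontal gyrus, orbital part (left)	ORBinf_L
50	Inferior frontal gyrus, orbital part (right)	ORBinf_R
51	Superior frontal gyrus, medial orbital (left)	ORBsupmed_L
52	Superior frontal gyrus, medial orbital (right)	ORBsupmed_R
53	Gyrus rectus (left)	REC_L
54	Gyrus rectus (right)	REC_R
55	Insula (left)	INS_L
56	Insula (right)	INS_R
57	Anterior cingulate and paracingulate gyri (left)	ACG_L
58	Anterior cingulate and paracingulate gyri (right)	ACG_R
59	Median cingulate and paracingulate gyri (left)	DCG_L
60	Median cingulate and paracingulate gyri (right)	DCG_R
61	Posterior cingulate gyrus (left)	PCG_L
62	Posterior cingulate gyrus (right)	PCG_R
63	Parahippocampal gyrus (left)	PHG_L
64	Parahippocampal gyrus (right)	PHG_R
65	Temporal pole: superior temporal gyrus (left)	TPOsup_L
66	Temporal pole: superior temporal gyrus (right)	TPOsup_R
67	Temporal pole: middle temporal gyrus (left)	TPOmid_L
68	Temporal pole: middle temporal gyrus (right)	TPOmid_R
69	Olfactory cortex (left)	OLF_L
70	Olfactory cortex (right)	OLF_R
71	Hippocampus (left)	HIP_L
72	Hippocampus (right)	HIP_R
73	Amygdala (left)	AMYG_L
74	Amygdala (right)	AMYG_R
75	Caudate nucleus (left)	CAU_L
76	Caudate nucleus (right)	CAU_R
77	Lenticular nucleus, putamen (left)	PUT_L
78	Lenticular nucleus, putamen (right)	PUT_R
79	Lenticular nucleus, pallidum (left)	PAL_L
80	Lenticular nucleus, pallidum (right)	PAL_R
81	Thalamus (left)	THA_L
82	Thalamus (right)	THA_R
83	Precentral gyrus (left)	PreCG_L
84	Precentral gyrus (right)	PreCG_R
85	Calcarine fissure and surrounding cortex (left)	CAL_L
86	Calcarine fissure and surrounding cortex (right)	CAL_R
87	Postcentral gyrus (left)	PoCG_L
88	Postcentral gyrus (right)	PoCG_R
89	Heschl gyrus (left)	HES_L
90	Heschl gyrus (right)	HES_R
91	Cerebelum_Crus1 (left)	CERcr1_L
92	Cerebelum_Crus1 (right)	CERcr1_R
93	Cerebelum_Crus2 (left)	CERcr2_L
94	Cerebelum_Crus2 (right)	CERcr2_R
95	Cerebelum_3 (left)	CER3_L
96	Cerebelum_3 (right)	CER3_R
97	Cerebelum_4_5 (left)	CER45_L
98	Cerebelum_4_5 (right)	CER45_R
99	Cerebelum_6 (left)	CER6_L
100	Cerebelum_6 (right)	CER6_R
101	Cerebelum_7b (left)	CER7_L
102	Cerebelum_7b (right)	CER7_R
103	Cerebelum_8 (left)	CER8_L
104	Cerebelum_8 (right)	CER8_R
105	Cerebelum_9 (left)	CER9_L
106	Cerebelum_9 (right)	CER9_R
107	Cerebelum_10 (left)	CER10_L
108	Cerebelum_10 (right)	CER10_R
109	Vermis_1_2	Ver1_2
110	Vermis_3	Ver3
111	Vermis_4_5	Ver4_5
112	Vermis_6	Ver6
113	Vermis_7	Ver7
114	Vermis_8	Ver8
115	Vermis_9	Ver9
116	Vermis_10	Ver10
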