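rank,icd3,label,cases,mean_cost_eur
1,I50,Heart failure,9924,3683
2,J18,Pneumonia (pathogen not specified),8503,3671
3,S72,Fracture of the femur,8029,7794
4,E86,Volume depletion,6579,2549
5,N39,Other diseases of the urinary system,6150,2613
6,S06,Intracranial injury,5054,2104
7,A41,Other sepsis,4508,4984
8,J69,Pneumonia due to solid and liquid substances,4486,4007
9,I63,Cerebral infarction,4410,6228
10,G40,Epilepsy,4149,3371
11,J44,Other chronic obstructive pulmonary disease,4125,4346
12,E11,Type 2 diabetes mellitus,3173,4197
13,K56,Paralytic ileus and intestinal obstruction without hernia,2913,4418
14,J20,Acute bronchitis,2563,2692
15,I70,Atherosclerosis,2487,6912
16,K92,Other diseases of the digestive system,2396,2277
17,S00,Superficial injury of the head,2362,1122
18,N17,Acute renal failure,2328,4375
19,S32,Fracture of the lumbar spine and pelvis,2162,4166
20,F05,Delirium not caused by alcohol or other psychotropic substances,2039,5915
21,J15,Pneumonia due to bacteria not classified elsewhere,2012,4723
22,N30,Cystitis,1833,2771
23,A09,Other and unspecified gastroenteritis and colitis of infectious and unspecified origin,1782,2210
24,R55,Syncope and collapse,1720,1933
25,F20,Schizophrenia,1691,8144
26,I10,Essential (primary) hypertension,1673,2069
27,I21,Acute myocardial infarction,1612,5000
28,K80,Cholelithiasis,1595,4847
29,K59,Other functional intestinal disorders,1586,1930
30,S42,Fracture of shoulder and upper arm,1407,4903
31,J22,Unspecified acute lower respiratory infection,1400,2923
32,A46,Erysipelas,1355,2894
33,G45,Transient cerebral ischemic attacks and related syndromes,1345,3493
34,K21,Gastro-esophageal reflux disease,1328,2215
35,K29,Gastritis and duodenitis,1319,2314
36,N13,Obstructive and reflux uropathy,1246,2813
37,I48,Atrial fibrillation and flutter,1176,2959
38,D50,Iron deficiency anemia,1159,3035
39,S22,"Fracture of rib(s), sternum and thoracic spine",1130,3263
40,A04,Other bacterial intestinal infections,1062,3950
41,L89,Pressure ulcer,1043,8282
42,T85,"Complications of other internal prosthetic devices, implants and grafts",986,3247
43,F06,Other mental disorders due to known physiological condition,969,6953
44,G20,Parkinson's disease,952,5167
45,C44,Other and unspecified malignant neoplasm of skin,874,3017
46,T84,"Complications of internal orthopedic prosthetic devices, implants and grafts",858,9410
47,E87,"Other disorders of fluid, electrolyte and acid-base balance",857,2851
48,I80,"Thrombosis, phlebitis and thrombophlebitis",847,2256
49,K57,Diverticular disease of intestine,845,4114
50,H25,Age-related cataract,830,1517
51,B99,Other and unspecified infectious diseases,819,2632
52,G30,Alzheimer's disease,815,5989
53,J96,Respiratory failure not elsewhere classified,761,9046
54,S82,"Fracture of lower leg, including ankle",753,4785
55,S52,Fracture of forearm,729,3218
56,I26,Pulmonary embolism,714,3917
57,N18,Chronic kidney disease,714,4542
58,K22,Other diseases of esophagus,707,3759
59,G41,Status epilepticus,677,5775
60,F25,Schizoaffective disorders,663,8356
61,S70,Superficial injury of hip and thigh,653,1510
62,R31,Hematuria,650,2084
63,D64,Other anemias,639,2810
64,R40,"Somnolence, stupor and coma",636,2220
65,F10,Alcohol related disorders,614,3334
66,S30,"Superficial injury of abdomen, lower back, pelvis and external genitals",602,1463
67,K52,Other and unspecified noninfective gastroenteritis and colitis,600,2600
68,T82,"Complications of cardiac and vascular prosthetic devices, implants and grafts",594,5690
69,T83,"Complications of genitourinary prosthetic devices, implants and grafts",586,1898
70,M54,Dorsalgia,576,2519
71,I61,Nontraumatic intracerebral hemorrhage,561,7477
72,C34,Malignant neoplasm of bronchus and lung,552,4163
73,K55,Vascular disorders of intestine,546,5838
74,R07,Pain in throat and chest,542,1260
75,R13,Aphagia and dysphagia,517,2202
76,C50,Malignant neoplasm of breast,507,4532
77,F33,Major depressive disorder recurrent,505,8731
78,K25,Gastric ulcer,504,4742
79,L03,Cellulitis and acute lymphangitis,487,2911
80,A08,Viral and other specified intestinal infections,479,2687
81,I74,Arterial embolism and thrombosis,476,7158
82,R10,Abdominal and pelvic pain,465,1478
83,I95,Hypotension,457,1802
84,T81,Complications of procedures not elsewhere classified,437,5231
85,G35,Multiple sclerosis,428,5181
86,I20,Angina pectoris,427,2805
87,M80,Osteoporosis with current pathological fracture,424,4484
88,J10,Influenza due to other identified influenza virus,423,3670
89,R26,Abnormalities of gait and mobility,413,4670
90,S02,Fracture of skull and facial bones,406,2631
91,F01,Vascular dementia,401,5352
92,R11,Nausea and vomiting,395,1786
93,C18,Malignant neoplasm of colon,383,8317
94,K62,Other diseases of anus and rectum,371,3256
95,K26,Duodenal ulcer,366,4268
96,J40,Bronchitis not specified as acute or chronic,365,2493
97,Z45,Encounter for adjustment and management of implanted device,363,3835
98,K83,Other diseases of biliary tract,338,3987
99,C67,Malignant neoplasm of bladder,334,3986
100,F07,Personality and behavioral disorders,317,6327
101,A49,Bacterial infection of unspecified site,293,2985
102,S01,Open wound of head,289,1007
103,R33,Retention of urine,275,1299
104,K40,Inguinal hernia,267,3366
105,S80,Superficial injury of knee and lower leg,258,2914
106,Z49,Encounter for care involving renal dialysis,252,8529
107,L02,"Cutaneous abscess, furuncle and carbuncle",215,3176
108,A40,Streptococcal sepsis,212,4641
109,R06,Abnormalities of breathing,206,1265
110,I44,Atrioventricular and left bundle-branch block,202,5528
111,K08,Other disorders of teeth and supporting structures,196,2362
112,T17,Foreign body in respiratory tract,195,3312
113,N20,Calculus of kidney and ureter,192,3554
114,I49,Other cardiac arrhythmias,191,5138
115,S20,Superficial injury of thorax,188,1563
116,I35,Nonrheumatic aortic valve disorders,187,7909
117,F32,Major depressive disorder single episode,181,5245
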