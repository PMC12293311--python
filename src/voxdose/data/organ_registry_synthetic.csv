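id,name,density,weight_class,H,C,N,O,Na,Mg,P,S,Cl,K,Ca,Fe,I
1,skin,1.09,weighted,0.100,0.204,0.042,0.645,0.002,0.0,0.001,0.002,0.003,0.001,0.0,0.0,0.0
2,brain,1.04,weighted,0.107,0.145,0.022,0.712,0.002,0.0,0.004,0.002,0.003,0.003,0.0,0.0,0.0
3,eye_lenses,1.07,unscored,0.096,0.195,0.057,0.646,0.001,0.0,0.001,0.003,0.001,0.0,0.0,0.0,0.0
4,salivary_glands,1.05,weighted,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
5,thyroid,1.05,weighted,0.104,0.119,0.024,0.745,0.002,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.001
6,oesophagus,1.03,weighted,0.106,0.115,0.022,0.751,0.001,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.0
7,lungs,0.26,weighted,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
8,breast,0.95,weighted,0.114,0.598,0.007,0.278,0.001,0.0,0.0,0.001,0.001,0.0,0.0,0.0,0.0
9,heart,1.05,remainder,0.104,0.139,0.029,0.718,0.001,0.0,0.002,0.002,0.002,0.003,0.0,0.0,0.0
10,liver,1.06,weighted,0.102,0.139,0.030,0.716,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
11,stomach,1.03,weighted,0.106,0.115,0.022,0.751,0.001,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.0
12,spleen,1.06,remainder,0.103,0.113,0.032,0.741,0.001,0.0,0.003,0.002,0.002,0.003,0.0,0.0,0.0
13,pancreas,1.04,remainder,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
14,kidneys,1.05,remainder,0.103,0.132,0.030,0.724,0.002,0.0,0.002,0.002,0.002,0.002,0.001,0.0,0.0
15,adrenals,1.03,remainder,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
16,small_intestine,1.03,remainder,0.106,0.115,0.022,0.751,0.001,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.0
17,colon_upper,1.03,weighted,0.106,0.115,0.022,0.751,0.001,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.0
18,colon_lower,1.03,weighted,0.106,0.115,0.022,0.751,0.001,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.0
19,bladder,1.04,weighted,0.105,0.096,0.026,0.761,0.002,0.0,0.002,0.002,0.003,0.003,0.0,0.0,0.0
20,gonads,1.04,weighted,0.106,0.099,0.020,0.766,0.002,0.0,0.001,0.002,0.002,0.002,0.0,0.0,0.0
21,red_marrow,1.03,weighted,0.105,0.414,0.034,0.439,0.0,0.0,0.002,0.002,0.002,0.001,0.0,0.001,0.0
22,bone_surface,1.18,weighted,0.085,0.404,0.058,0.367,0.001,0.001,0.034,0.002,0.002,0.001,0.044,0.001,0.0
23,skeleton,1.92,unscored,0.034,0.155,0.042,0.435,0.001,0.002,0.103,0.003,0.0,0.0,0.225,0.0,0.0
24,muscle,1.05,remainder,0.102,0.142,0.034,0.711,0.001,0.0,0.002,0.003,0.001,0.004,0.0,0.0,0.0
25,thymus,1.03,remainder,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
26,gall_bladder,1.03,remainder,0.106,0.115,0.022,0.751,0.001,0.0,0.001,0.001,0.002,0.001,0.0,0.0,0.0
27,prostate,1.04,remainder,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
28,oral_mucosa,1.05,remainder,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
29,lymph_nodes,1.03,remainder,0.102,0.110,0.033,0.745,0.001,0.0,0.001,0.002,0.003,0.002,0.0,0.001,0.0
30,extrathoracic,1.05,remainder,0.102,0.143,0.034,0.708,0.002,0.0,0.003,0.003,0.002,0.003,0.0,0.0,0.0
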