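aa,hydropathy_kd,aliphatic_coef,bulkiness,alpha_propensity,turn_propensity,interaction_index,residue_mass
A,1.8,100.0,11.50,1.489,0.788,-1.81,71.0788
C,2.5,0.0,13.46,0.966,0.965,-1.28,103.1388
D,-3.5,0.0,11.68,0.924,1.197,8.72,115.0886
E,-3.5,0.0,13.57,1.504,1.149,6.81,129.1155
F,2.8,0.0,19.80,1.195,0.624,-2.98,147.1766
G,-0.4,0.0,3.40,0.510,1.860,-0.94,57.0519
H,-3.2,0.0,13.69,1.003,0.970,4.66,137.1411
I,4.5,390.0,21.40,1.003,0.240,-4.92,113.1594
K,-3.9,0.0,15.71,1.172,1.302,5.55,128.1741
L,3.8,390.0,21.40,1.236,0.670,-4.92,113.1594
M,1.9,0.0,16.25,1.363,0.436,-2.35,131.1926
N,-3.5,0.0,12.82,0.772,1.572,6.64,114.1038
P,-1.6,0.0,17.43,0.492,1.415,0.0,97.1167
Q,-3.5,0.0,14.45,1.164,0.997,5.54,128.1307
R,-4.5,0.0,14.28,1.224,0.912,14.92,156.1875
S,-0.8,0.0,9.47,0.739,1.316,3.40,87.0782
T,-0.7,0.0,15.77,0.785,0.739,2.57,101.1051
V,4.2,290.0,21.57,0.990,0.387,-4.04,99.1326
W,-0.9,0.0,21.67,1.090,0.546,-2.33,186.2132
Y,-1.3,0.0,18.03,0.787,0.795,-0.14,163.1760
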