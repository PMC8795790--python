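# name: VSGETAWAY
# property_class: 3D-structural
# source: synthetic stand-in built from classical residue property scales (z-scored); not the original VSGETAWAY descriptor values
residue,c1,c2,c3,c4,c5,c6
A,-1.272,-1.549,-1.389,-0.487,1.494,-0.539
C,-0.791,-0.510,-0.974,-0.487,-1.067,0.439
D,-0.729,-0.123,-0.145,-0.487,0.036,-1.326
E,-0.069,0.332,0.269,-0.487,1.814,-1.788
F,1.175,0.917,1.099,1.949,0.462,0.954
G,-1.961,-2.003,-1.803,-0.487,-1.530,-0.756
H,0.288,0.591,0.684,1.949,0.000,-0.430
I,0.615,-0.186,-0.145,-0.487,0.285,1.552
K,0.660,0.301,0.269,-0.487,0.569,-0.783
L,0.615,-0.186,-0.145,-0.487,0.747,0.737
M,0.523,0.399,-0.145,-0.487,1.601,0.058
N,-0.656,-0.155,-0.145,-0.487,-1.174,-0.376
P,-0.690,-0.705,-0.560,-0.487,-1.530,-1.299
Q,0.061,0.300,0.269,-0.487,0.391,0.194
R,0.776,1.209,1.099,-0.487,-0.071,-0.267
S,-1.262,-1.031,-0.974,-0.487,-0.818,-0.756
T,-0.608,-0.576,-0.560,-0.487,-0.605,0.439
V,-0.030,-0.640,-0.560,-0.487,0.213,1.823
W,2.091,2.181,2.342,1.949,0.285,0.927
Y,1.264,1.435,1.513,1.949,-1.103,1.199
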