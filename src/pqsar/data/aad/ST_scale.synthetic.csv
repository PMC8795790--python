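# name: ST_scale
# property_class: topological
# source: synthetic stand-in built from classical residue property scales (z-scored); not the original ST_scale descriptor values
residue,c1,c2,c3,c4,c5,c6,c7,c8
A,-1.389,-1.565,-1.272,-1.549,-0.487,1.494,-0.539,0.767
C,-0.974,-0.719,-0.791,-0.510,-0.487,-1.067,0.439,1.001
D,-0.145,0.127,-0.729,-0.123,-0.487,0.036,-1.326,-1.008
E,0.269,0.973,-0.069,0.332,-0.487,1.814,-1.788,-1.008
F,1.099,0.127,1.175,0.917,1.949,0.462,0.954,1.101
G,-1.803,-1.565,-1.961,-2.003,-0.487,-1.530,-0.756,0.030
H,0.684,0.127,0.288,0.591,1.949,0.000,-0.430,-0.907
I,-0.145,0.127,0.615,-0.186,-0.487,0.285,1.552,1.671
K,0.269,1.819,0.660,0.301,-0.487,0.569,-0.783,-1.142
L,-0.145,0.127,0.615,-0.186,-0.487,0.747,0.737,1.436
M,-0.145,0.973,0.523,0.399,-0.487,1.601,0.058,0.800
N,-0.145,0.127,-0.656,-0.155,-0.487,-1.174,-0.376,-1.008
P,-0.560,-1.565,-0.690,-0.705,-0.487,-1.530,-1.299,-0.372
Q,0.269,0.973,0.061,0.300,-0.487,0.391,0.194,-1.008
R,1.099,1.819,0.776,1.209,-0.487,-0.071,-0.267,-1.342
S,-0.974,-0.719,-1.262,-1.031,-0.487,-0.818,-0.756,-0.104
T,-0.560,-0.719,-0.608,-0.576,-0.487,-0.605,0.439,-0.070
V,-0.560,-0.719,-0.030,-0.640,-0.487,0.213,1.823,1.570
W,2.342,0.127,2.091,2.181,1.949,0.285,0.927,-0.137
Y,1.513,0.127,1.264,1.435,1.949,-1.103,1.199,-0.271
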