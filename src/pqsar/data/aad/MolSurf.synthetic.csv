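# name: MolSurf
# property_class: quantum-chemical
# source: synthetic stand-in built from classical residue property scales (z-scored); not the original MolSurf descriptor values
residue,c1,c2,c3,c4,c5
A,-0.084,-0.014,-0.011,0.767,-1.549
C,-1.050,-0.539,-0.011,1.001,-0.510
D,1.738,-1.839,-2.188,-1.008,-0.123
E,1.477,-1.585,-2.188,-1.008,0.332
F,-1.161,-0.308,-0.011,1.101,0.917
G,0.251,-0.031,-0.011,0.030,-2.003
H,0.771,0.885,0.207,-0.907,0.591
I,-1.161,-0.003,-0.011,1.671,-0.186
K,1.106,2.100,2.166,-1.142,0.301
L,-1.273,-0.025,-0.011,1.436,-0.186
M,-0.976,-0.161,-0.011,0.800,0.399
N,1.217,-0.347,-0.011,-1.008,-0.155
P,-0.121,0.156,-0.011,-0.372,-0.705
Q,0.808,-0.212,-0.011,-1.008,0.300
R,0.808,2.676,2.166,-1.342,1.209
S,0.325,-0.195,-0.011,-0.104,-1.031
T,0.102,-0.240,-0.011,-0.070,-0.576
V,-0.901,-0.036,-0.011,1.570,-0.640
W,-1.087,-0.076,-0.011,-0.137,2.181
Y,-0.790,-0.206,-0.011,-0.271,1.435
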