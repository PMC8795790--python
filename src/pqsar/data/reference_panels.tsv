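panel	domain_class	domain_name	domain_index	species	n_valid
1	SH3	Amphiphysin	1/1	Human	884
2	SH3	Amphiphysin	1/1	Yeast	2032
3	SH3	Boi1	1/1	Yeast	1336
4	SH3	Boi2	1/1	Yeast	1312
5	SH3	Endophilin	1/1	Yeast	1998
6	SH3	Myosin5	1/1	Yeast	1139
7	SH3	Rvs167	1/1	Yeast	1369
8	SH3	Sho1	1/1	Yeast	1015
9	SH3	Yfr024	1/1	Yeast	1282
10	SH3	Yhr016c	1/1	Yeast	1348
11	PDZ	CALP	1/1	Human	80
12	PDZ	NHERF1	1/2	Human	77
13	PDZ	NHERF1	2/2	Human	80
14	PDZ	NHERF2	1/2	Human	80
15	PDZ	NHERF2	2/2	Human	80
16	PDZ	SYNA1	1/1	Human	56
17	PDZ	PSD95	1/1	Human	6068
18	14-3-3	14-3-3	1/1	Yeast	1163
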