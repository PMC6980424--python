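	A	C	G	U
A	2.22	-1.86	-1.46	-1.39
C	-1.86	1.16	-2.48	-1.05
G	-1.46	-2.48	1.03	-1.74
U	-1.39	-1.05	-1.74	1.65
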