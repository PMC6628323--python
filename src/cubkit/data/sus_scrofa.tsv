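aa	codon	rscu
F	TTT	0.79
F	TTC	1.21
L	TTA	0.32
L	TTG	0.67
L	CTT	1.35
L	CTC	1.35
L	CTA	0.33
L	CTG	2.68
I	ATT	0.91
I	ATC	1.67
I	ATA	0.42
V	GTT	0.57
V	GTC	1.07
V	GTA	0.34
V	GTG	2.03
S	TCT	0.99
S	TCC	1.5
S	TCA	0.73
S	TCG	0.39
S	AGT	0.77
S	AGC	1.62
P	CCT	1.05
P	CCC	1.46
P	CCA	0.94
P	CCG	0.56
T	ACT	0.83
T	ACC	1.68
T	ACA	0.92
T	ACG	0.57
A	GCT	0.96
A	GCC	1.8
A	GCA	0.74
A	GCG	0.5
Y	TAT	0.73
Y	TAC	1.27
H	CAT	0.7
H	CAC	1.3
Q	CAA	0.44
Q	CAG	1.56
N	AAT	0.79
N	AAC	1.21
K	AAA	0.76
K	AAG	1.24
D	GAT	0.8
D	GAC	1.2
E	GAA	0.72
E	GAG	1.28
C	TGT	0.79
C	TGC	1.21
R	CGT	0.44
R	CGC	1.31
R	CGA	0.6
R	CGG	1.29
R	AGA	1.12
R	AGG	1.23
G	GGT	0.57
G	GGC	1.46
G	GGA	0.91
G	GGG	1.05
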