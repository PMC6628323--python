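aa	codon	rscu
F	TTT	1.2
F	TTC	0.8
L	TTA	1.73
L	TTG	0.21
L	CTT	0.57
L	CTC	1.51
L	CTA	1.68
L	CTG	0.29
I	ATT	0.54
I	ATC	0.49
I	ATA	1.97
V	GTT	0.65
V	GTC	0.6
V	GTA	2.24
V	GTG	0.51
S	TCT	0.71
S	TCC	0.6
S	TCA	1.51
S	TCG	0.15
S	AGT	1.02
S	AGC	2
P	CCT	1.57
P	CCC	0.42
P	CCA	0.64
P	CCG	0.71
T	ACT	2.33
T	ACC	0.31
T	ACA	1.14
T	ACG	0.48
A	GCT	2.16
A	GCC	0.22
A	GCA	1.03
A	GCG	0.98
Y	TAT	1.14
Y	TAC	0.86
H	CAT	0.72
H	CAC	1.28
Q	CAA	1.5
Q	CAG	0.5
N	AAT	0.93
N	AAC	1.07
K	AAA	1.6
K	AAG	0.4
D	GAT	0.75
D	GAC	1.25
E	GAA	1.39
E	GAG	0.61
C	TGT	1.3
C	TGC	0.7
R	CGT	0.15
R	CGC	0.95
R	CGA	0.64
R	CGG	0.52
R	AGA	2.95
R	AGG	0.79
G	GGT	0.32
G	GGC	0.5
G	GGA	2.74
G	GGG	0.44
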