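aa	codon	rscu
F	TTT	1.1
F	TTC	0.9
L	TTA	0.93
L	TTG	0.32
L	CTT	0.79
L	CTC	0.99
L	CTA	1.74
L	CTG	1.22
I	ATT	0.84
I	ATC	0.6
I	ATA	1.56
V	GTT	0.55
V	GTC	0.6
V	GTA	1.81
V	GTG	1.04
S	TCT	0.96
S	TCC	0.83
S	TCA	1.28
S	TCG	0.59
S	AGT	1.61
S	AGC	0.73
P	CCT	0.6
P	CCC	0.86
P	CCA	1.9
P	CCG	0.65
T	ACT	0.69
T	ACC	0.65
T	ACA	2.08
T	ACG	0.58
A	GCT	0.76
A	GCC	1.07
A	GCA	1.6
A	GCG	0.57
Y	TAT	0.57
Y	TAC	1.43
H	CAT	0.56
H	CAC	1.44
Q	CAA	0.81
Q	CAG	1.19
N	AAT	0.77
N	AAC	1.23
K	AAA	1.38
K	AAG	0.62
D	GAT	0.6
D	GAC	1.4
E	GAA	1.22
E	GAG	0.78
C	TGT	0.88
C	TGC	1.12
R	CGT	0.48
R	CGC	0.88
R	CGA	0.82
R	CGG	0.3
R	AGA	2.8
R	AGG	0.71
G	GGT	0.62
G	GGC	0.55
G	GGA	2.21
G	GGG	0.61
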