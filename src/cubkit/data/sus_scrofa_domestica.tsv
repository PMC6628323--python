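aa	codon	rscu
F	TTT	0.59
F	TTC	1.41
L	TTA	0.3
L	TTG	0.49
L	CTT	1.41
L	CTC	1.41
L	CTA	0.28
L	CTG	2.92
I	ATT	1.22
I	ATC	1.45
I	ATA	0.34
V	GTT	0.34
V	GTC	1.45
V	GTA	0.17
V	GTG	2.04
S	TCT	1.1
S	TCC	1
S	TCA	2.45
S	TCG	0.55
S	AGT	0.25
S	AGC	0.66
P	CCT	0.84
P	CCC	1.59
P	CCA	0.91
P	CCG	0.66
T	ACT	0.77
T	ACC	1.2
T	ACA	1.62
T	ACG	0.41
A	GCT	0.7
A	GCC	1.03
A	GCA	1.92
A	GCG	0.36
Y	TAT	0.69
Y	TAC	1.31
H	CAT	0.6
H	CAC	1.4
Q	CAA	0.29
Q	CAG	1.71
N	AAT	0.82
N	AAC	1.18
K	AAA	0.91
K	AAG	1.09
D	GAT	0.81
D	GAC	1.19
E	GAA	1.24
E	GAG	0.76
C	TGT	0.81
C	TGC	1.19
R	CGT	0.4
R	CGC	1.09
R	CGA	0.27
R	CGG	0.77
R	AGA	2.75
R	AGG	0.71
G	GGT	0.31
G	GGC	0.84
G	GGA	1.78
G	GGG	1.07
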