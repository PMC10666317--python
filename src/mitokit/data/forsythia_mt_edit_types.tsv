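from_codon	to_codon	count
CAC	TAC	6
CAT	TAT	15
CGC	TGC	7
CGT	TGT	29
ACA	ATA	3
ACC	ATC	1
ACG	ATG	3
ACT	ATT	3
CGG	TGG	28
TCA	TTA	72
TCC	TTC	31
TCG	TTG	38
TCT	TTT	38
CAA	TAA	1
CGA	TGA	1
CCA	TCA	6
CCC	TCC	6
CCG	TCG	3
CCT	TCT	20
CCA	CTA	44
CCC	CTC	9
CCC	TTC	6
CCG	CTG	31
CCT	CTT	20
CCT	TTT	14
CTC	TTC	4
CTT	TTT	10
GCC	GTC	2
GCG	GTG	7
GCT	GTT	2
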