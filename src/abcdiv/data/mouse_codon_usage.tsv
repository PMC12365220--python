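# organism: mouse
# Approximate Mus musculus codon usage (occurrences per 1000 codons).
# Family fractions are left as '-' and derived from per_thousand at load time.
codon	amino_acid	family_fraction	per_thousand
TTT	F	-	17.2
TTC	F	-	21.8
TTA	L	-	6.7
TTG	L	-	13.4
CTT	L	-	13.4
CTC	L	-	20.2
CTA	L	-	8.1
CTG	L	-	39.5
ATT	I	-	15.4
ATC	I	-	22.5
ATA	I	-	7.4
ATG	M	-	22.8
GTT	V	-	10.7
GTC	V	-	15.4
GTA	V	-	7.4
GTG	V	-	28.4
TCT	S	-	16.2
TCC	S	-	18.1
TCA	S	-	11.8
TCG	S	-	4.2
CCT	P	-	18.4
CCC	P	-	18.2
CCA	P	-	17.3
CCG	P	-	6.2
ACT	T	-	13.7
ACC	T	-	19.0
ACA	T	-	16.0
ACG	T	-	5.6
GCT	A	-	20.0
GCC	A	-	26.0
GCA	A	-	15.8
GCG	A	-	6.4
TAT	Y	-	12.2
TAC	Y	-	16.1
TAA	*	-	1.0
TAG	*	-	0.8
CAT	H	-	10.6
CAC	H	-	15.3
CAA	Q	-	12.0
CAG	Q	-	34.1
AAT	N	-	15.6
AAC	N	-	20.3
AAA	K	-	21.9
AAG	K	-	33.6
GAT	D	-	21.0
GAC	D	-	26.0
GAA	E	-	27.0
GAG	E	-	39.4
TGT	C	-	11.4
TGC	C	-	12.3
TGA	*	-	1.6
TGG	W	-	12.5
CGT	R	-	4.7
CGC	R	-	9.4
CGA	R	-	6.6
CGG	R	-	10.2
AGT	S	-	12.7
AGC	S	-	19.7
AGA	R	-	12.1
AGG	R	-	12.2
GGT	G	-	11.4
GGC	G	-	21.2
GGA	G	-	16.8
GGG	G	-	15.2
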