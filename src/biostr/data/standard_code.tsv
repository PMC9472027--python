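codon	aa	is_start
AAA	K	0
AAC	N	0
AAG	K	0
AAU	N	0
ACA	T	0
ACC	T	0
ACG	T	0
ACU	T	0
AGA	R	0
AGC	S	0
AGG	R	0
AGU	S	0
AUA	I	0
AUC	I	0
AUG	M	1
AUU	I	0
CAA	Q	0
CAC	H	0
CAG	Q	0
CAU	H	0
CCA	P	0
CCC	P	0
CCG	P	0
CCU	P	0
CGA	R	0
CGC	R	0
CGG	R	0
CGU	R	0
CUA	L	0
CUC	L	0
CUG	L	1
CUU	L	0
GAA	E	0
GAC	D	0
GAG	E	0
GAU	D	0
GCA	A	0
GCC	A	0
GCG	A	0
GCU	A	0
GGA	G	0
GGC	G	0
GGG	G	0
GGU	G	0
GUA	V	0
GUC	V	0
GUG	V	0
GUU	V	0
UAA	*	0
UAC	Y	0
UAG	*	0
UAU	Y	0
UCA	S	0
UCC	S	0
UCG	S	0
UCU	S	0
UGA	*	0
UGC	C	0
UGG	W	0
UGU	C	0
UUA	L	0
UUC	F	0
UUG	L	1
UUU	F	0
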