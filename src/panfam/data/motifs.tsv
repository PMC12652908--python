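name	iupac	category
TATA-box	TATAWAW	core
CAAT-box	CCAAT	core
ABRE	ACGTGKC	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
as-1	TGACGTCA	hormone
AuxRR-core	GGTCCAT	hormone
P-box	CCTTTTG	hormone
GARE-motif	TCTGTTG	hormone
TATC-box	TATCCCA	hormone
TCA-element	CCATCTTTTT	hormone
ERE	ATTTCAAA	hormone
MBS	CAACTG	stress
LTR	CCGAAA	stress
TC-rich-repeats	ATTCTCTAAC	stress
ARE	AAACCA	stress
WUN-motif	AAATTTCCT	stress
DRE-CRT	RCCGAC	stress
STRE	AGGGG	stress
W-box	TTGACC	stress
G-box	CACGTG	light
Box-4	ATTAAT	light
GT1-motif	GGTTAA	light
I-box	GATAAGR	light
MRE	AACCTA	light
AE-box	AGAAACAA	light
CAT-box	GCCACT	development
O2-site	GATGAYRTGR	development
GCN4-motif	TGAGTCA	development
RY-element	CATGCATG	development
circadian	CAAAGATATC	development
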