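# Control-region conserved-element library (editable configuration).
# IUPAC consensus strings approximating the avian CR literature; these are
# working consensi, not published sequences -- tune per study system.
# domain: expected domain (I/II/III), used for reporting only.
name	iupac	max_mismatch	domain
ETAS1	TACATAWTATGTAYTA	2	I
F	ATGTAYGGCYCATTTG	2	II
E	AGGGRTCYYTCTAGTA	2	II
D	CCTGGTTCYTATTTCA	2	II
C	GTGTTRGGGGTATTAC	2	II
CSBa	CAAACCCCCCTACCCC	2	II
CSBb	CCCTAAACCGGTACTA	2	II
BirdBox	TTCGGTTAATGCWGGT	2	II
CSB1	TTTGACATCTGGTTCC	2	III
# elements of the general vertebrate CR model that are often absent in
# raptors; kept so their absence is reported rather than forced
ETAS2	GCGTACCATAAATGCA	1	I
CSB2	TAAACCCCTCTACCCA	1	III
CSB3	TGCCAAACCCCAAAAA	1	III
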