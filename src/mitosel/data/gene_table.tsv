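# Ancestral avian mitochondrial gene order (chicken-like), starting at trnF.
# kind: PCG | tRNA | rRNA | control_region; strand: H | L
# length: default span used by the synthetic-genome generator (nt)
name	kind	strand	length
trnF	tRNA	H	71
rrnS	rRNA	H	975
trnV	tRNA	H	72
rrnL	rRNA	H	1590
trnL2	tRNA	H	75
ND1	PCG	H	978
trnI	tRNA	H	72
trnQ	tRNA	L	72
trnM	tRNA	H	69
ND2	PCG	H	1038
trnW	tRNA	H	72
trnA	tRNA	L	69
trnN	tRNA	L	73
trnC	tRNA	L	67
trnY	tRNA	L	71
COX1	PCG	H	1551
trnS2	tRNA	L	71
trnD	tRNA	H	69
COX2	PCG	H	684
trnK	tRNA	H	70
ATP8	PCG	H	168
ATP6	PCG	H	684
COX3	PCG	H	785
trnG	tRNA	H	69
ND3	PCG	H	351
trnR	tRNA	H	69
ND4L	PCG	H	297
ND4	PCG	H	1379
trnH	tRNA	H	69
trnS1	tRNA	H	69
trnL1	tRNA	H	72
ND5	PCG	H	1818
CYTB	PCG	H	1142
trnT	tRNA	H	70
trnP	tRNA	L	70
ND6	PCG	L	522
trnE	tRNA	L	69
CR	control_region	H	1214
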