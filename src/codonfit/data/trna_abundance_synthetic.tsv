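# Synthetic stand-in for measured intracellular tRNA concentrations (uM) at
# ~2.5 doublings per hour. Isoacceptor structure and wobble recognition sets
# follow E. coli conventions; concentrations are plausible values chosen so
# that optimal codons of highly expressed genes have large decoding pools.
trna_id	concentration_uM	codons
Ala1	13.0	GCA,GCG,GCU
Ala2	2.5	GCC,GCU
Arg2	12.0	CGU,CGC,CGA
Arg3	1.2	CGG
Arg4	1.5	AGA,AGG
Arg5	1.0	AGG
Asn	3.5	AAC,AAU
Asp	6.5	GAC,GAU
Cys	4.0	UGC,UGU
Gln1	2.0	CAA
Gln2	2.5	CAG
Glu	12.0	GAA,GAG
Gly1	2.7	GGG
Gly2	11.0	GGC,GGU
Gly3	2.5	GGA,GGG
His	1.6	CAC,CAU
Ile1	9.0	AUC,AUU
Ile2	0.6	AUA
Leu1	11.0	CUG
Leu2	2.4	CUC,CUU
Leu3	1.7	CUA,CUG
Leu4	4.8	UUG
Leu5	2.6	UUA,UUG
Lys	5.2	AAA,AAG
Met	2.2	AUG
Phe	2.5	UUC,UUU
Pro1	2.3	CCG
Pro2	1.9	CCC,CCU
Pro3	1.5	CCA,CCU,CCG
Ser1	3.2	UCA,UCU,UCG
Ser2	0.9	UCG
Ser3	3.9	AGC,AGU
Ser5	2.1	UCC,UCU
Thr1	2.2	ACC,ACU
Thr2	1.4	ACG
Thr4	2.1	ACA,ACU,ACG
Trp	1.9	UGG
Tyr	3.0	UAC,UAU
Val1	11.0	GUA,GUG,GUU
Val2	1.8	GUC,GUU
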