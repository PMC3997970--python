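# Rank-specific recognition codes: rank 1 (strongest) to 64 for the SP1
# three-finger domain and five second-finger alpha-helix mutants.
rank	SP1	CB1	MR14	MQ91	MQ135	MQ151
1	CGG	CCC	GAG	AGG	GGA	AGG
2	GCG	GAG	GGA	CGG	GAC	GGA
3	CGT	GGT	GTG	GGA	GAG	AAG
4	GGC	AGG	GAA	GAG	TAA	GAG
5	TTG	GGA	GGG	AAG	GGG	GTA
6	TGG	TAA	GGT	GGC	GGT	AGT
7	GAG	CAG	GTA	GTG	AGA	TGA
8	CCC	GTG	AGG	AGA	GAT	GTG
9	TAG	GGG	GGC	ATG	GTG	TTG
10	CCG	TGG	GTT	AAT	AGT	GCA
11	AGG	TGT	TGG	AAA	GGC	GGG
12	GGT	TAT	CCC	GGT	GTA	GGT
13	GAC	CAT	AGT	CAG	AGG	CGT
14	GTG	ATG	CGG	GGG	TGA	TTT
15	GGA	GTT	GAT	GAC	CGA	GCG
16	AGT	CGT	TGA	GAA	GCT	GCT
17	TAA	CGG	AAG	AGT	GTT	GAT
18	CAG	GTC	GAC	ACA	GCG	TGG
19	GTC	TAG	GCG	ATT	ATG	GTC
20	GCT	TCG	TGC	ACC	GCA	AAT
21	TAT	CAC	TTG	GCG	AGC	ATT
22	GTA	GAA	TAG	GCT	TGT	TCT
23	GAT	GAC	GCA	TAG	CGT	CGG
24	GCA	GTA	TTT	ATA	GAA	TGT
25	AAT	GCG	CGC	GTA	ATT	GGC
26	CGC	AGA	CGT	CAA	ACT	TAG
27	TCT	CGC	GTC	CGT	TCA	TAT
28	TCG	GGC	ATG	TAA	ACC	ACT
29	TAC	AAG	AGA	GTC	CGG	AGA
30	CCT	ACA	CAG	TGG	ACA	TTC
31	CAA	CCG	CCT	GCA	TGG	CCC
32	GTT	AAT	GCT	GCC	CAA	GTT
33	GGG	GAT	ATA	CCC	CCT	AGC
34	CAT	AGT	CAA	CGA	GCC	ATA
35	TGT	CAA	CTG	GAT	AAT	TGC
36	TCA	GCT	TGT	ACT	AAG	TTA
37	GCC	TGA	CGA	TGA	ATA	TCC
38	TGA	TCC	CAT	CAT	TTT	AAA
39	TTT	CCT	CTA	CCG	CGC	ACA
40	CGA	CGA	AAT	ACG	ACG	CGA
41	ATG	AAA	CCG	GTT	AAA	GAC
42	AAG	TTG	CTT	AGC	TTA	AAC
43	ACT	CCA	TAA	CCT	AAC	ATG
44	CTG	CTG	AGC	CAC	TAG	ACC
45	ATA	TCA	TAT	CGC	TTC	CGC
46	AGA	TAC	ATT	CTA	GTC	GCC
47	TTA	CTA	ACA	TAC	CAT	TCA
48	TCC	ATT	CAC	AAC	CCC	CTT
49	CCA	CTT	ACT	TCG	TAC	CTG
50	TGC	AGC	CTC	TAT	TGC	CCG
51	TTC	ACT	ACG	CCA	CAG	GAA
52	AGC	ATA	TTA	TGC	CAC	TAA
53	ACA	TTA	CCA	CTT	TTG	TAC
54	ACG	GCC	TCA	TCT	TAT	CAA
55	CAC	TTT	ACC	CTG	CTT	CAG
56	ATT	CTC	GCC	TCA	TCG	CTA
57	CTA	TCT	AAA	TCC	CCA	ACG
58	ATC	AAC	AAC	CTC	CCG	CAT
59	CTT	ACC	TAC	TGT	CTG	CTC
60	GAA	ACG	TCG	TTG	TCT	CCA
61	CTC	ATC	TCT	ATC	ATC	CCT
62	ACC	GCA	ATC	TTT	TCC	CAC
63	AAC	TGC	TCC	TTA	CTC	TCG
64	AAA	TTC	TTC	TTC	CTA	ATC
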