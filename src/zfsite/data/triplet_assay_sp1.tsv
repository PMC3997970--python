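# EMSA band-shift quantification for the 64 second-finger triplets of SP1,
# with exact-match counts of GGG+triplet+GGG in the HuRef human genome assembly.
# Rows are ordered by descending P32 count (the published presentation order).
triplet	p32_count	occurrences
CGG	4570	16697
GCG	3450	22741
CGT	3125	6508
GGC	2850	16087
TTG	2320	28372
TGG	2300	55636
GAG	2180	58721
CCC	1900	6153
TAG	1850	14922
CCG	1850	8662
AGG	1750	41257
GGT	1440	38721
GAC	1215	5109
GTG	1200	69427
GGA	1175	50364
AGT	1150	26799
TAA	1100	9037
CAG	1010	34437
GTC	950	6246
GCT	800	42489
TAT	660	7319
GTA	630	15656
GAT	560	23908
GCA	555	40076
AAT	550	17749
CGC	500	4098
TCT	475	16364
TCG	450	7161
TAC	380	1172
CCT	300	27004
CAA	300	15503
GTT	280	24314
GGG	260	18460
CAT	250	14458
TGT	245	20901
TCA	238	23485
GCC	235	12890
TGA	230	24010
TTT	225	16500
CGA	225	5420
ATG	188	28958
AAG	188	36175
ACT	187	16928
CTG	150	38542
ATA	124	7850
AGA	123	38448
TTA	110	10717
TCC	110	2733
CCA	80	22765
TGC	75	4411
TTC	73	1854
AGC	65	6704
ACA	63	26050
ACG	62	6423
CAC	50	3769
ATT	50	11132
CTA	40	9049
ATC	30	1919
CTT	20	15023
GAA	10	36693
CTC	10	4500
ACC	0	3170
AAC	0	2925
AAA	0	29730
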