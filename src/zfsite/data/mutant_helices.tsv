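# Alpha-helical residues (9 positions) of the SP1 second finger and mutants.
# substituted_positions: 0-based indices of the exchanged residues.
name	residues	substituted_positions
SP1	RSDELKRHK	
CB1	HSSRLIRHE	0,3,5,8
MR14	RSSTLIQHK	3,6
MQ91	QSSYLIKHK	0,3,6
MQ135	QSSHLIQHK	0,3,6
MQ151	QSSYLTQHK	0,3,6
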