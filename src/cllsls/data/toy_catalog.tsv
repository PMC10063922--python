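subset_id	ighv_genes	cdr3_length	consensus_cdr3	motif	motif_offset	mutation_class	light_chain_gene
T1	IGHV1-69,IGHV5-51	13	ARDKGYYSYGMDV	GYYS	4	U	IGKV2-30
T2	IGHV3-21	9	ARDANGMDV	ANG	3	M	IGLV3-21
T3	IGHV4-34,IGHV4-39	16	ARGQWLVPAAYYYMDV	WLVP	4	U
T4	IGHV3-23	12	ARVGSDTAMFDY	DTXM	5	M
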