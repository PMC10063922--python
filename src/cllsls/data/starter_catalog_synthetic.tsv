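subset_id	ighv_genes	cdr3_length	consensus_cdr3	motif	motif_offset	mutation_class	light_chain_gene	provenance
1	IGHV1-69	13	ARSGYYDSSGMDV	YYDS	4	U		gene+class literature; consensus/motif SYNTHETIC placeholder
2	IGHV3-21	9	ARDKDSMDV	KDS	3	M	IGLV3-21	gene, class, IGLV3-21 restriction literature; consensus/motif SYNTHETIC placeholder
4	IGHV4-34	20	ARGYGSGSYANDAFDLWFDP	SYAN	7	M	IGKV2-30	gene, class, IGKV2-30 restriction literature; consensus/motif SYNTHETIC placeholder
8	IGHV4-39	19	ARHSGYSSGWYYEGAWFDP	SSGW	6	U		gene+class literature; consensus/motif SYNTHETIC placeholder
12	IGHV1-69	15	ARGGDYDYVWGMDVW	DYDY	4	U		class literature; gene/consensus/motif SYNTHETIC placeholder
14	IGHV4-4	18	ARGYYYGSGSPNWFDPAY	GSGS	6	U		consensus/motif/class SYNTHETIC placeholder
28A	IGHV1-2	14	ARDHSSGWYGGMDV	SSGW	4	U		class literature; gene/consensus/motif SYNTHETIC placeholder
31	IGHV3-33	17	ARDGGYYDFWSGYYTDV	YDFW	6	U		class literature; gene/consensus/motif SYNTHETIC placeholder
59	IGHV1-58	11	ARDPYYYYMDV	PYYY	3	U		class literature; gene/consensus/motif SYNTHETIC placeholder
73	IGHV3-23	14	ARQGDIVATTPFDY	IVAT	5	M		class literature; gene/consensus/motif SYNTHETIC placeholder
77	IGHV3-7	12	ARGSNWDYFDYW	NWDY	4	M	IGLV10-54	class + IGLV10-54 restriction literature; gene/consensus/motif SYNTHETIC placeholder
148B	IGHV2-5	15	ARLTGTTVVSPFDYW	TTVV	5	M		consensus/motif/class SYNTHETIC placeholder
169	IGHV3-48	9	ARDQDSMDV	QDS	3	M	IGLV3-21	class + IGLV3-21 restriction literature; gene/consensus/motif SYNTHETIC placeholder
201	IGHV3-9	13	ARDRGGYSSWMDV	GYSS	5	M	IGLV1-44	IGLV1-44 restriction literature; gene/consensus/motif/class SYNTHETIC placeholder
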