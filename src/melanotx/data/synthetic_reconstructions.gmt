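PI3K_AKT_MTOR	pi3k_akt	AKT1	AKT2	AKT3	PIK3CA	PIK3CB	PIK3R1	MTOR	RPS6KB1	EIF4EBP1	PDPK1	PTEN	FOXO3	GSK3B	TSC1	TSC2	RHEB	RICTOR	RPTOR	AKT1S1	DEPTOR
PROLIFERATION	proliferation	MKI67	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	PLK1	PCNA	TOP2A	CCNB1	CCNA2	CDK1	BUB1	AURKA	AURKB	FOXM1	TYMS	RRM2	CDC20
CELLCYCLE_G1	cell_cycle_phase:G1	CCNE1	CCNE2	CDC6	CDT1	E2F1	MCM10
CELLCYCLE_S	cell_cycle_phase:S	RRM2	CDC45	GINS2	CLSPN	TYMS	FEN1
CELLCYCLE_G2	cell_cycle_phase:G2	CCNA2	CDK1	TOP2A	CENPF	KIF11	NDC80
CELLCYCLE_M	cell_cycle_phase:M	CCNB1	CCNB2	PLK1	AURKA	AURKB	BUB1	CDC20
TSOI_UNDIFFERENTIATED	subtype:undifferentiated	AXL	EGFR	ZEB1	SMAD3	TGFBI	SERPINE1	FOSL1	ITGA3
TSOI_NEURAL_CREST_LIKE	subtype:neural_crest_like	NGFR	SOX2	TFAP2B	GFRA1	L1CAM	PDGFRB
TSOI_TRANSITORY	subtype:transitory	TFAP2A	ERBB3	DCT	SEMA6A	TNC	SOX10
TSOI_MELANOCYTIC	subtype:melanocytic	MITF	PMEL	TYR	TYRP1	MLANA	SLC45A2	OCA2
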