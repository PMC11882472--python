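MAPK_TARGETS_WAGLE	mapk_targets	SPRY2	SPRY4	DUSP4	DUSP6	CCND1	EPHA2	EPHA4	ETV4	ETV5	PHLDA1
QUIESCENCE_G0	quiescence	CDKN1B	CDKN1A	NR2F1
APOPTOSIS	apoptosis	BCL2	BCL2L1	BAK1	MCL1	CASP3	CASP8
FERROPTOSIS	ferroptosis	GPX4	HMOX1	LPCAT5	ACSL5	TFRC	NOX1	NOX4	HSPB1
INTRINSIC_RESISTANCE	resistance_panel	HMOX1	BIRC5	CTSS	ENG	ICAM1	LGALS3	SPARC	DKK1
ABC_TRANSPORTERS	abc_transporters	ABCB1	ABCC2	ABCD1	ABCG2
DIFF_MARKER_PANEL	marker_panel	MITF	SOX10	POU3F2	ATF4	AXL	EGFR	ERBB3	NGFR	SMAD3	ZEB1
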