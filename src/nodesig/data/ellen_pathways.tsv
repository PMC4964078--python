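pathway	symbol	direction
Gene Expression	EGR1	good
Gene Expression	FOS	good
Gene Expression	JUN	good
Gene Expression	NAT10	good
Gene Expression	RPL11	good
Gene Expression	ZFP36	good
Gene Expression	EEF2	good
Gene Expression	LITAF	good
Gene Expression	POLR2E	good
Gene Expression	POLR3E	good
Gene Expression	RPLP2	good
Gene Expression	RPS15	good
Gene Expression	RPS23	good
Gene Expression	RPL38	poor
Gene Expression	RPS11	poor
Proliferation	KIDINS220	good
Proliferation	PIK3R1	good
Proliferation	ZFP36L2	good
Proliferation	CDIPT	good
Proliferation	CXCL12	good
Proliferation	JTB	poor
Proliferation	SERPINB3	poor
Proliferation	NUCKS1	poor
Proliferation	SNRPE	poor
Proliferation	SPDEF	poor
Proliferation	TXN	poor
Immune Response	FOS	good
Immune Response	CXCL12	good
Immune Response	HLA-DPA1	good
Immune Response	JAK1	good
Immune Response	PCBP2	good
Immune Response	FKBP4	poor
Immune Response	MTDH	poor
Immune Response	NUCKS1	poor
Cell Migration	SPTBN1	good
Cell Migration	CYFIP1	good
Cell Migration	CXCL12	good
Cell Migration	S100P	poor
Cell Migration	ARF6	poor
Cell Migration	CSTA	poor
Cell Migration	NUCKS1	poor
Apoptosis	JUN	good
Apoptosis	SGK1	good
Apoptosis	LITAF	good
Apoptosis	TNFRSF10B	good
Apoptosis	GLTSCR2	good
Apoptosis	ITM2B	good
Apoptosis	S100G	poor
Stress Response	DUSP1	good
Stress Response	ABAT	good
Stress Response	CIRBP	good
Stress Response	GLTSCR2	good
Stress Response	GPX4	good
Metabolism	GPX4	good
Metabolism	FLOT1	poor
Metabolism	SQLE	poor
Metabolism	COX5B	poor
Metabolism	GPR172A	poor
Epigenetics	NCOR1	good
Epigenetics	SMARCA2	good
Epigenetics	NAT10	poor
Epigenetics	H3F3A	poor
Angiogenesis	ACTC1	poor
Angiogenesis	MB	poor
Differentiation	DPYSL2	good
Differentiation	RAI2	good
Cell Cycle	SFN	poor
PTM and Trafficking	DUSP1	good
Cytoskeleton	KRT10	poor
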