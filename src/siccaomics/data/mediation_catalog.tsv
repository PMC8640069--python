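snp_id	feature_id	gene_label	layer	beta_qtl	beta_disease	or_	p
rs9275569	cg08099136	PSMB8	methylation	-0.018	-0.062	2.03	1.57e-08
rs1051047	cg14880222	IFI44	methylation	0.027	-0.036	0.54	0.0127
rs9838739	cg03879629	CCR_cluster	methylation	-0.046	-0.071	1.71	0.0242
rs6962291	cg12013713	PARP12	methylation	-0.017	-0.048	1.32	0.0270
rs1054684	ENSG00000166278	C2	expression	0.300	0.911	4.04	2.16e-13
rs4947258	ENSG00000204267	TAP2	expression	0.168	0.478	3.53	2.90e-12
rs3117106	ENSG00000240065	PSMB9	expression	0.139	0.287	2.22	1.23e-07
rs2523425	ENSG00000204713	TRIM27	expression	-0.069	-0.136	1.51	7.32e-04
rs4731531	ENSG00000128604	IRF5	expression	0.084	0.192	1.46	0.0014
rs4482223	ENSG00000174444	RPL4	expression	0.101	-0.195	0.53	0.0019
rs3799378	ENSG00000124508	BTN2A2	expression	0.096	0.228	1.54	0.0025
rs9261518	ENSG00000234127	TRIM26	expression	-0.113	0.154	0.60	0.0029
rs10849822	ENSG00000175970	UNC119B	expression	-0.066	-0.161	1.48	0.0075
rs6660288	ENSG00000162614	NEXN	expression	0.143	0.685	1.36	0.0156
rs57570581	ENSG00000002549	LAP3	expression	-0.216	0.867	0.75	0.0187
rs9348883	ENSG00000204516	MICB	expression	-0.174	0.242	0.46	0.0276
rs76397273	ENSG00000154451	GBP5	expression	-0.288	0.701	0.67	0.0301
rs289953	ENSG00000184898	RBM43	expression	0.183	0.378	1.29	0.0398
rs11080327	ENSG00000166750	SLFN5	expression	0.222	0.255	1.28	0.0401
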