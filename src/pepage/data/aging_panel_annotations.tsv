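peptide_id	sequence	accession	protein_name	start_aa	stop_aa
27944	EEHTQSPIFVGKVVDPTHK	Q00897	Alpha-1-antitrypsin 1-4	395	413
19004	GQpGAkGEpGDTGVKGD	P11087	Collagen alpha-1(I) chain	810	826
19814	GLpGPAGPpGEAGKpGEQ	P11087	Collagen alpha-1(I) chain	633	650
26939	GQPGAKGEpGDTGVKGDAGPpGP	P11087	Collagen alpha-1(I) chain	810	832
27161	GQpGAKGEpGDTGVKGDAGPpGP	P11087	Collagen alpha-1(I) chain	810	832
20728	GmPGSpGGpGNDGKpGpPG	P08121	Collagen alpha-1(III) chain	536	554
25169	QGIpGTGGPpGENGKpGEpGP	P08121	Collagen alpha-1(III) chain	640	660
22729	pGpAGpKGETGEmGLSGLP	Q8K4G2	Collagen alpha-1(XXIII) chain	357	375
7489	VSINKELQNS	P61110	Kidney androgen-regulated protein	25	34
10290	VSINKELQNSI	P61110	Kidney androgen-regulated protein	25	35
22456	SINKELQNSIIDLLNS	P61110	Kidney androgen-regulated protein	26	41
19014	VVGQLKADEDPIMGF	P61971	Nuclear transport factor 2	85	99
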