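rs_number	locus	major_allele	minor_allele	risk_allele
rs6314	HTR2A	C	T	C
rs1328674	HTR2A	C	T	T
rs548234	PRDM1	T	C	C
rs4781003	CIITA	C	T	T
rs4535211	PLCL2	G	A	A
rs10431908	CIITA	A	G	G
rs544167	C2	G	T	G
rs12746613	FCGR2A	C	T	T
rs4810485	CD40	G	T	G
rs10498441	NID2	A	G	A
rs10499194	OLIG3,TNFAIP3	C	T	C
rs2064476	HLA-DPB2	A	G	A
rs706778	IL2RA	C	T	T
rs2736340	BLK	A	G	G
rs26232	C5orf30	C	T	C
rs540386	TRAF6	C	T	C
rs231707	C4orf8	G	A	A
rs10402677	CEACAM1	G	A	A
rs42041	CDK6	C	G	G
rs2024301	CLEC4A;POU5F1P3	A	T	T
rs3807306	IRF5	A	C	A
rs10488631	IRF5;TNPO3	T	C	C
rs3761847	TRAF1/C5	A	G	G
rs7026551	C5	A	C	C
rs11586238	CD2,CD58	C	G	G
rs231735	CTLA4	G	T	G
rs13017599	REL	A	G	G
rs394581	TAGAP	T	C	T
rs2263484	C21orf74	A	C	C
rs6682654	CD244			
rs6859219	ANKRD55	C	A	C
rs13031237	REL	A	C	C
rs934734	SPRED2	A	G	G
rs11676922	AFF3	A	T	T
rs3087243	CTLA4	G	A	G
rs1678542	KIF5A	C	G	C
rs951500	CCL21	A	G	A
rs892188	GLP-1;FDX1L;ICAM5	C	T	T
rs1133104	CLEC4A;POU5F1P3	G	T	T
rs1980422	CD28	T	C	C
rs1859341	CEACAM8	A	G	G
rs3087456	CIITA	A	G	G
rs2271077	GALNTL2	A	G	A
rs2377422	CLEC4A;POU5F1P3	C	T	T
rs2476601	PTPN22	C	T	T
rs2812378	CCL21;C9orf144B	A	G	G
rs2240340	PADI4	C	T	T
rs6416647	CIITA	T	C	C
rs3890745	MMEL1	T	C	T
rs4272626	NHLH2	C	T	T
rs10258735	RPA3	A	G	G
rs3093023	CCR6	G	A	A
rs3218253	IL2RB	G	A	A
rs6822844	IL2,IL21	G	T	G
rs7234029	PTPN2	A	G	G
rs6457620	HLA-DRA	G	C	G
rs6920220	OLIG3,TNFAIP3	G	A	A
rs10413014	CEACAM8	A	G	G
rs7574865	STAT4	G	T	T
rs10468473	MAP2K4	G	A	A
rs10410147	CEACAM8	G	A	A
rs10919563	PTPRC	G	A	G
rs4750316	DKFZp667F0711/PRKCQ	G	C	G
rs2523451	MICA	A	G	G
rs6457617	HLA-DQ	C	T	C
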