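id	control	aionfh	log2fc	pvalue	fdr	symbol
ENSG00000127603	896.1243	56.55429	-3.98599	0.006348	1	MACF1
ENSG00000203782	41.74714	616.2157	3.883686	0.007813	1	LORICRIN
ENSG00000174469	34.36	610.1686	4.150406	0.007913	1	CNTNAP2
ENSG00000196705	20.50571	535.6743	4.707258	0.015625	1	ZNF431
ENSG00000127481	642.4114	0.001	-19.2931	0.015776	1	UBR4
ENSG00000171914	615.4014	0.001	-19.2312	0.015776	1	TLN2
ENSG00000197245	2.771429	445.0943	7.327337	0.015776	1	FAM110D
ENSG00000282872	5.542857	445.0943	6.327337	0.015776	1	C1orf232
ENSG00000095015	18.56571	481.4043	4.696536	0.03125	1	MAP3K1
ENSG00000164742	15.79429	457.4171	4.856036	0.03125	1	ADCY1
ENSG00000176771	29.65	371.8471	3.648606	0.03125	1	NCKAP5
ENSG00000229017	11.08429	481.4043	5.440661	0.03125	1	-
ENSG00000081248	34.36	470.8943	3.776601	0.031466	1	CACNA1S
ENSG00000111799	28.81857	407.4486	3.821547	0.031466	1	COL12A1
ENSG00000137936	369.0429	0.001	-18.4934	0.031466	1	BCAR3
ENSG00000146416	21.33714	488.91	4.51813	0.031466	1	AIG1
ENSG00000152591	17.73429	485.6657	4.775351	0.031466	1	DSPP
ENSG00000175718	44.51857	468.0629	3.394223	0.031466	1	RBMXL3
ENSG00000177694	699.3343	0.001	-19.4156	0.031466	1	NAALADL2
ENSG00000182095	2.771429	342.3229	6.948584	0.031466	1	TNRC18
ENSG00000225937	343.4171	0.001	-18.3896	0.031466	1	-
ENSG00000234170	885.8443	0.001	-19.7567	0.031466	1	-
ENSG00000242086	49.22857	438.5086	3.155037	0.031466	1	-
ENSG00000249001	30.75857	485.6657	3.980903	0.031466	1	-
ENSG00000102910	181.8057	804.5586	2.1458	0.038574	1	LONP2
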