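gene	ensembl	chromosome	cds_start	cds_end	xci_status	y_homolog_or_pseudogene	aorta_expression_rpkm	valve_development
TIMP1	ENSG00000102265	X	47442814	47446090	Variable	no	423.6	yes
RBM3	ENSG00000102317	X	48433568	48435474	Variable	no	48.96	unknown
UBA1	ENSG00000130985	X	47058201	47074328	Active	no	41.44	unknown
INE2	ENSG00000281371	X	15805712	15805712	Active	no	12.36	unknown
AP1S2	ENSG00000182287	X	15845447	15870647	Mostly Active	no	8.701	unknown
GEMIN8	ENSG00000046647	X	14027031	14039597	Mostly Active	no	6.69	unknown
CA5B	ENSG00000169239	X	15768146	15800787	Variable	no	5.198	unknown
NHS	ENSG00000188158	X	17653686	17750584	Mostly Active	no	4.852	unknown
TRAPPC2	ENSG00000196459	X	13732525	13738082	Mostly Active	no	4.289	unknown
CA5BP1	ENSG00000186312	X	15721474	15721474	Active	no	3.813	unknown
CTPS2	ENSG00000047230	X	16608915	16721025	Mostly Active	no	3.593	unknown
INE1	ENSG00000224975	X	47065254	47065254	Active	no	2.09	unknown
TCEANC	ENSG00000176896	X	13680627	13681683	Mostly Active	no	0.4852	unknown
PPEF1	ENSG00000086717	X	18725899	18845605	Variable	no	0.05353	unknown
GRPR	ENSG00000126010	X	16142076	16170768	Mostly Active	no	0.02957	unknown
FAM9C	ENSG00000187268	X	13056559	13061908	Active	no	0.005627	unknown
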