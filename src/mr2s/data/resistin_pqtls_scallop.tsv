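rsid	chromosome	position	gene	locus_class	effect_allele	other_allele	eaf	beta	se	pvalue	n	published_r2	published_f	status	note
rs17405635	2	43355763	ZFP36L2	trans	A	G	0.26	0.08	0.011	6.6e-14	20793	0.002	41.7	analysis
rs7589428	2	43561771	THADA	trans	A	G	0.51	0.063	0.0095	4.6e-11	21747	0.002	43.6	analysis
rs6775731	3	128306894	RPN1	trans	T	C	0.3	-0.063	0.011	3.2e-09	21747	0.002	43.6	analysis
rs2239619	6	52453220	TRAM2	trans	A	C	0.62	-0.053	0.0097	4.1e-08	21749	0.001	21.8	analysis
rs77691416	6	144354119	PLAGL1	trans	A	C	0.91	0.12	0.016	7.9e-14	18353	0.002	36.8	analysis
rs73008259	6	144411338	SF3B5	trans	A	G	0.053	0.19	0.02	3.7e-21	16199	0.004	65.0	analysis
rs445	7	92408370	CDK6	trans	T	C	0.1	-0.085	0.015	3.3e-08	18353	0.001	18.4	analysis
rs10103048	8	130602281	GSDMC	trans	A	C	0.42	0.06	0.0096	5.2e-10	21747	0.002	43.6	analysis
rs3087852	17	38137364	PSMD3	trans	A	G	0.46	-0.086	0.0094	6.6e-20	21749	0.004	87.3	analysis
rs34861192	19	7733575	RETN	cis	A	G	0.017	1.10	0.054	7.8e-89	15136	0.040	630.6	analysis
rs3745367	19	7734511	RETN	cis	A	G	0.24	0.12	0.012	7.5e-23	18353	0.005	92.2	analysis
rs10401670	19	7742802	MCEMP1	cis	T	C	0.43	0.15	0.012	9e-37	16221	0.011	180.4	analysis
rs4134826	19	7692076	XAB2	cis	T	C	0.86	-0.089	0.014	2.6e-10	18353	0.002	36.8	analysis
rs199752470	19	7735000	RETN	cis	C	T	0.004	0.45	0.08	2.0e-08	15136			excluded_missing_outcome	summary fields are synthetic placeholders; variant unavailable in both outcome datasets, no proxy
rs7746716	6	130000000	SAMD3	trans	A	T	0.48	0.06	0.01	3.0e-08	21747			excluded_palindromic	MAF 0.48 as published; remaining fields are synthetic placeholders; palindromic with ambiguous strand
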