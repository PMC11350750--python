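gene_symbol	probe_name	snp_id	consequence	protein_effect	gerp_gt2	constrained	regulatory	phenotype	breed_differs	chrom	position	gerp_score	regulatory_type	consequence_extra
ABI2	BIEC2_421048	rs69153418	intronic variant	0	0	1	0	0	0	3	200000000	0.8	none
ADGRA3	BIEC2_848365	rs68508249	upstream gene variant	0	0	0	1	0	0	3	201000000	0.5	enhancer
C18H2orf88	BIEC2_417365	rs69126368	intronic variant	0	0	1	0	0	1	18	67027762	1.5	none
CAPN1	CUHSNP00133513	rs396701927	missense variant	1	1	1	0	0	0	3	202000000	4.15	none
CAST	BIEC2_277089	rs68930623	intronic variant	0	0	0	1	0	0	3	203000000	0.5	enhancer
DNAH7	Affx-102281324	rs396935555	missense variant	1	0	0	0	0	1	3	204000000	0.5	none
ENSECAG00000052525	GGP_100_BODY_SIZE_ECA3	rs68603064	intronic variant	0	0	0	1	0	1	3	107374136	0.5	enhancer
FAM184B	BIEC2_808625	rs68454110	intronic variant	0	0	0	1	0	1	3	205000000	0.5	enhancer
FAM184B	BIEC2_808581	rs68534807	intronic variant	0	0	0	1	0	0	3	206000000	0.5	enhancer
GULP1	UKUL3220	18_65173441_T/C	missense variant	1	1	1	0	1	0	18	65173441	4.81	none	5 prime UTR variant
GULP1	CUHSNP00150635	18_65288583_A/C	3 prime UTR variant	0	1	0	0	0	0	18	65288583	3.2	none
IGF1R	BIEC2-44702	rs68514854	intronic variant	0	0	0	1	1	1	3	207000000	0.5	open_chromatin
LASP1	BIEC2_144152	rs68875002	intronic variant	0	0	0	1	1	1	3	208000000	0.72	enhancer
LASP1	BIEC2_144165	rs68876315	intronic variant	0	0	0	1	0	1	3	209000000	0.5	enhancer
LASP1	GGP_103_BODY_SIZE_ECA11	rs68876319	intronic variant	0	0	0	1	0	0	11	23334511	0.5	enhancer
LDB2	BIEC2_808856	rs68525653	intronic variant	0	1	0	0	0	0	3	210000000	3.0	none
LDB2	BIEC2-808833	rs68525607	intronic variant	0	0	0	1	0	0	3	211000000	0.5	enhancer
LGI2	UKUL843	rs1147560021	3 prime UTR variant	0	1	0	0	0	1	3	212000000	2.7	none
MSTN	BIEC2_417365	rs69126368	intronic variant	0	0	1	0	1	1	18	67027762	1.5	none
PCDH7	UKUL834	rs68555658	missense variant	1	1	0	0	0	1	3	213000000	2.83	none
PCDH7	UKUL835	rs1147724321	missense variant	1	1	0	0	0	0	3	214000000	3.84	none
PI4K2B	CUHSNP00004551	rs1141209077	stop-lost	1	0	0	0	0	0	3	215000000	0.5	none
PPARGC1A	BIEC2_848001	rs68672779	intronic variant	0	1	0	0	1	0	3	216000000	3.57	none
QDPR	BIEC2_808653	rs68520444	intronic variant	0	0	0	1	0	1	3	217000000	0.5	enhancer
RAPH1	BIEC2_421054	rs69153424	intronic variant	0	0	1	0	1	0	3	218000000	0.8	none
SEPSECS	BIEC2_806764	rs68670656	5 prime UTR variant	0	0	0	1	1	0	3	219000000	0.5	promoter
SLIT2	CUHSNP00004551	rs68593800	splice donor region variant	1	0	1	0	1	0	3	220000000	0.5	none
ZNF804A	BIEC2_416678	rs69192315	missense variant	1	0	0	0	0	0	3	221000000	0.5	none
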