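snp_id	breed	allele1	allele2
rs68603064	P	C	C
rs68603064	AM	T	T
rs68454110	P	C	C
rs68454110	AM	T	T
rs68514854	P	G	A
rs68514854	AM	A	A
rs68875002	P	T	T
rs68875002	AM	C	C
rs69126368	P	A	G
rs69126368	AM	G	G
rs68555658	P	T	G
rs68555658	AM	G	G
rs68520444	P	A	A
rs68520444	AM	A	G
rs396935555	P	C	T
rs396935555	AM	T	T
rs1147560021	P	C	T
rs1147560021	AM	T	T
rs68876315	P	A	A
rs68876315	AM	G	G
rs69153418	P	A	A
rs69153418	AM	A	A
rs68508249	P	C	C
rs68508249	AM	C	C
rs396701927	P	G	G
rs396701927	AM	G	G
rs68930623	P	T	T
rs68930623	AM	T	T
rs68534807	P	C	C
rs68534807	AM	C	C
18_65173441_T/C	P	T	T
18_65173441_T/C	AM	T	T
18_65288583_A/C	P	A	A
18_65288583_A/C	AM	A	A
rs68876319	P	A	A
rs68876319	AM	A	A
rs68525653	P	G	G
rs68525653	AM	G	G
rs68525607	P	C	C
rs68525607	AM	C	C
rs1147724321	P	T	T
rs1147724321	AM	T	T
rs1141209077	P	A	A
rs1141209077	AM	A	A
rs68672779	P	C	C
rs68672779	AM	C	C
rs69153424	P	G	G
rs69153424	AM	G	G
rs68670656	P	T	T
rs68670656	AM	T	T
rs68593800	P	C	C
rs68593800	AM	C	C
rs69192315	P	A	A
rs69192315	AM	A	A
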