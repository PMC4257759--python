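snp	risk_allele	gene	locus
rs4129267	T	IL6R	1q21.3
rs10508372	C	LOC338591	10p14
rs9500927	T	HLA-DOA	6p21.32
rs9900000	A	SYNGENE1	16q14
rs9900001	C	SYNGENE2	5q17
rs9900002	C	SYNGENE3	17q21
rs9900003	A	SYNGENE4	12q32
rs9900004	A	SYNGENE5	12q23
rs9900005	A	SYNGENE6	2q26
rs9900006	T	SYNGENE7	20q26
rs9900007	A	SYNGENE8	4q25
rs9900008	T	SYNGENE9	11q34
rs9900009	G	SYNGENE10	18q12
rs9900010	G	SYNGENE11	12q19
rs9900011	C	SYNGENE12	8q26
rs9900012	G	SYNGENE13	22q35
rs9900013	A	SYNGENE14	11q22
rs9900014	G	SYNGENE15	12q34
rs9900015	A	SYNGENE16	1q21
rs9900016	G	SYNGENE17	9q34
rs9900017	C	SYNGENE18	15q22
rs9900018	G	SYNGENE19	22q25
rs9900019	C	SYNGENE20	11q25
rs9900020	T	SYNGENE21	6q27
rs9900021	G	SYNGENE22	11q11
rs9900022	T	SYNGENE23	15q14
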