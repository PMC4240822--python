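chrom	pos	ref	alt	gene	hgvs_c	sift	polyphen2	pmut_nn	pmut_reliability	panther_subpsec	panther_pdel	ponp2_prob	ponp2_se	mutpred_prob
chr2	208989018	C	A	CRYGD	c.70C>A	0.10	0.084	0.0936	8	-2.35974	0.34519	0.479	0.332	0.840
chr1	147380102	T	C	GJA8	c.20T>C	0.00	0.991	0.8749	7	-4.3388	0.79148	0.947	0.050	0.918
chr1	147380375	A	C	GJA8	c.293A>C	0.00	1.000	0.7822	5	-3.98807	0.72871	0.444	0.090	0.889
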