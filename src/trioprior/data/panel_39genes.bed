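chr21	44589141	44592914	CRYAA
chr11	111779396	111784798	CRYAB
chr17	27573405	27580952	CRYBA1
chr2	219854911	219858127	CRYBA2
chr22	27018000	27026000	CRYBA4
chr22	26995242	27007756	CRYBB1
chr22	25615488	25627836	CRYBB2
chr22	25598654	25612423	CRYBB3
chr2	209034362	209038130	CRYGA
chr2	209007624	209012628	CRYGB
chr2	208992656	208994574	CRYGC
chr2	208986372	208990000	CRYGD
chr3	186254280	186260507	CRYGS
chr13	20716014	20738125	GJA3
chr1	147379240	147402128	GJA8
chr12	56843515	56850557	MIP
chr19	51881202	51889874	LIM2
chr20	17474551	17550543	BFSP1
chr3	133119243	133191559	BFSP2
chr10	17270258	17279592	VIM
chr16	67197287	67203849	HSF4
chr10	103989945	104001231	PITX3
chr16	79627745	79634622	MAF
chr1	47881743	47885085	FOXE3
chr11	31806340	31839509	PAX6
chr8	72109668	72274467	EYA1
chr1	16450832	16482582	EPHA2
chr9	100174404	100242657	TDRD7
chr3	45959395	46037764	FYCO1
chr10	91190535	91294613	SLC16A12
chr17	73754020	73761819	GALK1
chr4	6271577	6304992	WFS1
chr20	32399110	32442173	CHMP4B
chr19	49468558	49470135	FTL
chrX	17393543	17754103	NHS
chr6	10492223	10629368	GCNT2
chr7	141251078	141354209	AGK
chr21	47608190	47648788	LSS
chr19	38397845	38699019	SIPA1L3
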