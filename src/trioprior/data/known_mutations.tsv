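gene	hgvs_c	hgvs_p	note
CRYGD	c.70C>A	p.Pro24Thr	recurrent coralliform-cataract mutation
GJA8		p.Val79Leu	second transmembrane domain
GJA8		p.Pro88Ser	second transmembrane domain
GJA8		p.Pro88Gln	second transmembrane domain
GJA8		p.Pro88Thr	second transmembrane domain
SLC16A12	c.49T>G	p.Trp17Gly	age-related cataract association (rs3740030)
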