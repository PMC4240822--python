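>GJA8/1-40
MLKGSILPTAELKGSIVPTAELKGSIVPTAELKGSIVPTA
>Pan_troglodytes
CLKGSILPTHECKGSCVPTAELKGIIVPTAELKGSIVPTA
>Mus_musculus
MLKGSILPTAELKGSIVPSAMLKGFIVPTAEYKGKIIPTL
>Rattus_norvegicus
MLKGSILPTAELKGKIVNTAELKGSIVPTAEAKGSIVPKA
>Bos_taurus
MLKGKILPGAELHGSIVPTAELKGSIVPTAEFHGAIVPTA
>Gallus_gallus
VPKGSILPTGELKGSIVPTAWLKGSIVPTAELKGIIVPTA
>Danio_rerio
MLKGSILPTVELKTSIVPTAELKGSVVHTAELKGSIVPTM
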