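>GJA8/80-120
AELKGSIVPTAELKGSIVHTAELKGSIVPTAELKGSIVPTA
>Pan_troglodytes
AELKGSIVPTAELRGSIVHTAELKGSIVPTAELKGSIVPTA
>Mus_musculus
AELKFSIVPTAELKGSIVHTAELKGSIVPTAEKKGHIVPDA
>Rattus_norvegicus
PELKGTIVPTAELKGSQVHTAELKGSIVPTIELKGSIVPYA
>Bos_taurus
YELKGSIVPTAELKVSIYHTAELPGSIVPTAELKGSILPTS
>Gallus_gallus
AELKGSIVWTADLKGSIVHWAELNGSIYPTAELKGSIVPTA
>Danio_rerio
TWLKGVIVPTAELKGSIVHTAELKGSIVPTANLKGSIVPNA
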