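>CRYGD/10-45
AELKGSIVPTAELKPSIVPTAELKGSIVPTAELKGS
>Pan_troglodytes
AELKGSIVPTAEEKPSIVPTAELKGSIVEDAELKGS
>Mus_musculus
AELLGSIVMQAELKSSIVPTAELKGSIKPVAELKGS
>Rattus_norvegicus
AELKGSIVPTAELKSSIVPTADLKHSLVPTAELKGS
>Bos_taurus
FELKGSMVPTANLKTSVVPTAELTGSIVPTAELKGS
>Gallus_gallus
AELKGSIVPTAELKTSIVPTWEEKGSVVPTAELKGS
>Danio_rerio
AELKGSIQPTAELDTSIVPTAELKGSVMATHELKGF
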