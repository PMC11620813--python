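family,fc,fiv_printed
Amaranthaceae,11,20
Anacardiaceae,8,15
Annonaceae,13,24
Apocynaceae,18,33
Asphodelaceae,21,38
Asteraceae,7,13
Caricaceae,6,11
Combretaceae,5,9
Cucurbitaceae,14,26
Euphorbiaceae,22,40
Fabaceae,46,84
Lamiaceae,10,18
Loganiaceae,25,46
Meliaceae,13,24
Menispermaceae,20,36
Moraceae,9,16
Musaceae,3,6
Myrtaceae,34,62
Olacaceae,18,33
Oleaceae,7,13
Pedaliaceae,8,15
Phyllanthaceae,24,44
Rhamnaceae,8,15
Rubiaceae,19,35
Rutaceae,26,47
Sapindaceae,12,22
Solanaceae,5,9
Zingiberaceae,36,66
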