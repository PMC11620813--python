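taxon,family,FC,U,rfc_printed,uv_printed
Chenopodium opulifolium,Amaranthaceae,11,10,0.200,0.182
Mangifera indica,Anacardiaceae,8,16,0.145,0.291
Hexalobus monopetalus,Annonaceae,13,21,0.236,0.382
Diplorhynchus condylocarpon,Apocynaceae,6,9,0.109,0.164
Strophanthus eminii,Apocynaceae,12,23,0.218,0.418
Aloe vera,Asphodelaceae,21,14,0.382,0.255
Ageratum conyzoides,Asteraceae,7,10,0.127,0.182
Carica papaya,Caricaceae,6,8,0.109,0.145
Combretum pisoniiflorum,Combretaceae,5,5,0.091,0.091
Momordica charantia,Cucurbitaceae,14,21,0.255,0.382
Ricinus communis,Euphorbiaceae,14,13,0.255,0.236
Spirostachys africana,Euphorbiaceae,8,8,0.145,0.145
Cassia abbreviata,Fabaceae,29,17,0.527,0.309
Delonix elata,Fabaceae,11,18,0.200,0.327
Dichrostachys cinerea,Fabaceae,4,4,0.073,0.073
Entada abyssinica,Fabaceae,29,37,0.527,0.673
Erythrina abyssinica,Fabaceae,5,5,0.091,0.091
Piliostigma thonningii,Fabaceae,5,6,0.091,0.109
Vachellia nilotica,Fabaceae,10,17,0.182,0.309
Clerodendrum myricoides,Lamiaceae,10,11,0.182,0.200
Strychnos mitis,Loganiaceae,16,16,0.291,0.291
Strychnos potatorum,Loganiaceae,11,20,0.200,0.364
Trichilia emetica,Meliaceae,13,13,0.236,0.236
Cissampelos pareira,Menispermaceae,20,15,0.364,0.273
Ficus thonningii,Moraceae,9,25,0.164,0.455
Musa paradisiaca,Musaceae,3,6,0.055,0.109
Eucalyptus globulus,Myrtaceae,17,28,0.309,0.509
Psidium guajava,Myrtaceae,7,14,0.127,0.255
Syzygium aromaticum,Myrtaceae,18,36,0.327,0.655
Ximenia caffra,Olacaceae,18,31,0.327,0.564
Schrebera trichoclada,Oleaceae,7,12,0.127,0.218
Sesamum angolense,Pedaliaceae,8,15,0.145,0.273
Bridelia micrantha,Phyllanthaceae,16,12,0.291,0.218
Phyllanthus amarus,Phyllanthaceae,9,9,0.164,0.164
Ziziphus mucronata,Rhamnaceae,8,5,0.145,0.091
Crossopteryx febrifuga,Rubiaceae,6,10,0.109,0.182
Vangueria infausta,Rubiaceae,15,30,0.273,0.545
Citrus aurantifolia,Rutaceae,19,12,0.345,0.218
Citrus limon,Rutaceae,26,17,0.473,0.309
Zanha africana,Sapindaceae,12,27,0.218,0.491
Solanum incanum,Solanaceae,5,7,0.091,0.127
Zingiber officinale,Zingiberaceae,36,34,0.655,0.618
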