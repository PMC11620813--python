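taxon,family,local_name,origin,life_form,parts_used,source,ailments,iucn_category,scientific_name,voucher,preparation_notes,preparation_codes,administration_codes
Chenopodium opulifolium,Amaranthaceae,Mwoshafedha,native,herb,leaf,wild,influenza,NoRecord,Chenopodium opulifolium Schrad. ex W.D.J.Koch & Ziz,UR39,"Decoction drunk, steam inhalation",decoction|steam inhalation,oral|inhalation
Mangifera indica,Anacardiaceae,Mwembe,introduced,tree,seed|leaf,cultivated,coughs|colds|asthma,DD,Mangifera indica L.,UR26,Decoction drunk,decoction,oral
Hexalobus monopetalus,Annonaceae,Mkuwa,native,tree,leaf,wild,colds|coughs|bronchitis,LC,Hexalobus monopetalus (A.Rich.) Engl. & Diels,UR19,Decoction drunk,decoction,oral
Diplorhynchus condylocarpon,Apocynaceae,Msongati,native,shrub,root,wild,chronic coughs|pneumonia|tuberculosis,LC,Diplorhynchus condylocarpon (Müll.Arg.) Pichon,UR32,Concoction drunk,other,oral
Strophanthus eminii,Apocynaceae,Mvelevele,native,tree,root,wild,influenza|coughs,NoRecord,Strophanthus eminii Asch. ex Pax.,UR27,Decoction drunk,decoction,oral
Aloe vera,Asphodelaceae,Mlovera,introduced,herb,whole plant,wild,covid-19|sore throat|coughs|asthma,NoRecord,Aloe vera (L.) Burm.f.,UR29,Peeled leaves eaten for sore throat and cough; infusion drunk for asthma,infusion|other,oral
Ageratum conyzoides,Asteraceae,Msendawazi,introduced,herb,root|flower,wild,asthma|coughs|colds,LC,Ageratum conyzoides L.,UR07,Infusion of powdered roots drunk for asthma; flowerheads mixed with Ocimum tenuiflorum for coughs and cold,infusion,oral
Carica papaya,Caricaceae,Mpapai,introduced,tree,leaf|flower,cultivated,covid-19|bronchitis,DD,Carica papaya L.,UR37,Decoction of young leaves drunk for COVID-19; infusion of flowers drunk for bronchitis,decoction|infusion,oral
Combretum pisoniiflorum,Combretaceae,Mlama,native,tree,bark,wild,asthma,NoRecord,Combretum pisoniiflorum (Klotzsch) Engl.,UR31,Crush when mixed with salt,other,oral
Momordica charantia,Cucurbitaceae,Umotomoto,native,herb,leaf,both,asthma|tuberculosis,NoRecord,Momordica charantia L.,UR25,Decoction drunk,decoction,oral
Ricinus communis,Euphorbiaceae,Mnyonyo,introduced,shrub,leaf|root,wild,coughs,NoRecord,Ricinus communis L.,UR34,Decoction drunk,decoction,oral
Spirostachys africana,Euphorbiaceae,Mtomboti,native,tree,bark,wild,influenza,LC,Spirostachys africana Sond.,UR04,Chew and swallow the juice,chew,oral
Cassia abbreviata,Fabaceae,Muzoka,native,tree,bark,wild,pneumonia,LC,Cassia abbreviata Oliv.,UR35,Decoction drunk,decoction,oral
Delonix elata,Fabaceae,Mutangala,native,shrub,root,both,coughs|asthma,LC,Delonix elata (L.) Gamble,UR17,Decoction drunk,decoction,oral
Dichrostachys cinerea,Fabaceae,Mkulagembe,native,shrub,leaf,both,coughs,LC,Dichrostachys cinerea (L.) Wight & Arn.,UR38,Infusion drunk,infusion,oral
Entada abyssinica,Fabaceae,Mfutwamila,native,shrub,bark,both,colds|coughs,LC,Entada abyssinica Steud. ex A.Rich.,UR33,Decoction drunk,decoction,oral
Erythrina abyssinica,Fabaceae,Mlinzi,native,tree,bark|root,both,asthma,LC,Erythrina abyssinica Lam.,UR24,Decoction of pounded parts drunk,decoction,oral
Piliostigma thonningii,Fabaceae,Mkindwambogo,introduced,tree,fruit,wild,coughs,NoRecord,Piliostigma thonningii (Schumach.) Milne-Redh.,UR18,Chew and swallow the juice,chew,oral
Vachellia nilotica,Fabaceae,Mdubilo,native,tree,bark,wild,asthma|coughs,LC,Vachellia nilotica (L.) P.J.H.Hurter & Mabb.,UR30,Decoction drunk,decoction,oral
Clerodendrum myricoides,Lamiaceae,Mpugambu,native,tree,root,wild,asthma|coughs,EN,Clerodendrum myricoides (Hochst.) R.Br. ex Vatke.,UR36,Powdering of roots,powder,oral
Strychnos mitis,Loganiaceae,Mwangajini,native,tree,leaf,wild,whooping coughs,NoRecord,Strychnos mitis S.Moore,UR15,Decoction drunk,decoction,oral
Strychnos potatorum,Loganiaceae,Mgwegwe,native,tree,root|leaf|seed,wild,coughs|bronchitis,NoRecord,Strychnos potatorum L.f.,UR13,Decoction of roots and leaves for coughs; decoction of seed drunk for bronchitis,decoction,oral
Trichilia emetica,Meliaceae,Mtimaji,native,tree,root|bark,both,pneumonia|colds,LC,Trichilia emetica Vahl,UR05,Decoction drunk,decoction,oral
Cissampelos pareira,Menispermaceae,Mkulawanti,native,herb,rhizome,wild,coughs,NoRecord,Cissampelos pareira L.,UR11,Decoction drunk,decoction,oral
Ficus thonningii,Moraceae,Mlundalunda,native,tree,leaf,both,colds|sore throat|tuberculosis,LC,Ficus thonningii Blume,UR03,Decoction drunk,decoction,oral
Musa paradisiaca,Musaceae,Mgomba,introduced,herb,leaf,cultivated,colds|bronchitis,NoRecord,Musa paradisiaca L.,UR09,Dried leaves made into syrup and drunk,other,oral
Eucalyptus globulus,Myrtaceae,Mkalatusi,introduced,tree,leaf,both,covid-19|bronchial complaints,LC,Eucalyptus globulus Labill.,UR20,Steam inhalation,steam inhalation,inhalation
Psidium guajava,Myrtaceae,Mpera,introduced,tree,leaf,cultivated,coughs|influenza,LC,Psidium guajava L.,UR28,Infusion drunk,infusion,oral
Syzygium aromaticum,Myrtaceae,Mkarafuu,introduced,tree,flower,cultivated,coughs|influenza,NoRecord,Syzygium aromaticum (L.) Merr. & L.M.Perry,UR21,Powdering then mix with tea,powder,oral
Ximenia caffra,Olacaceae,Mtundadamu,native,tree,leaf|root,both,coughs|tonsillitis,LC,Ximenia caffra Sond.,UR01,Extracts of leaves gargled for tonsillitis; infusion of roots with leaves drunk for coughs,infusion|other,oral|topical
Schrebera trichoclada,Oleaceae,Mputika,native,tree,leaf,wild,coughs|influenza,LC,Schrebera trichoclada Welw.,UR41,Chew and swallow the juice,chew,oral
Sesamum angolense,Pedaliaceae,Mulendagwawima,native,herb,root,both,coughs|colds,NoRecord,Sesamum angolense Welw.,UR23,Infusion drunk,infusion,oral
Bridelia micrantha,Phyllanthaceae,Mtemela,native,tree,root,wild,coughs,LC,Bridelia micrantha (Hochst.) Baill.,UR40,Infusion drunk,infusion,oral
Phyllanthus amarus,Phyllanthaceae,Mbondo,introduced,herb,whole plant,both,coughs,NoRecord,Phyllanthus amarus Schumach. & Thonn.,UR16,Decoction combined with honey drunk,decoction,oral
Ziziphus mucronata,Rhamnaceae,Kagowole,native,tree,bark,both,coughs,LC,Ziziphus mucronata Willd.,UR14,Infusion drunk,infusion,oral
Crossopteryx febrifuga,Rubiaceae,Msasambeke,native,tree,root,both,coughs|influenza,LC,Crossopteryx febrifuga (Afzel. ex G.Don) Benth.,UR22,Concoction drunk,other,oral
Vangueria infausta,Rubiaceae,Mfulara,native,shrub,root,both,pneumonia|coughs,LC,Vangueria infausta Burch.,UR12,Warm decoction drunk,decoction,oral
Citrus aurantifolia,Rutaceae,Mndimu,introduced,tree,leaf,cultivated,asthma,LC,Citrus aurantifolia (Christm.) Swingle,UR08,"Decoction mixed with honey and egg, then drunk",decoction,oral
Citrus limon,Rutaceae,Mlimao,introduced,tree,fruit,cultivated,coughs,LC,Citrus limon (L.) Burm.f,UR10,"Decoct, then mix with Allium sativum",decoction,oral
Zanha africana,Sapindaceae,Mkalya,native,tree,root|bark,wild,colds|tonsillitis,NoRecord,Zanha africana (Radlk.) Exell.,UR02,Decoction of roots drunk; powder of bark used as snuff,decoction|powder,oral|other
Solanum incanum,Solanaceae,Ndulele,native,herb,root,both,coughs|sore throat,LC,Solanum incanum L.,UR42,Chew or swallow the sap,chew,oral
Zingiber officinale,Zingiberaceae,Tangawizi,introduced,herb,whole plant,cultivated,coughs|influenza,DD,Zingiber officinale Roscoe,UR06,Decoction drunk,decoction,oral
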