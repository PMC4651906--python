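clade,min_ma,max_ma
Metazoa,552.85,833
Eumetazoa,552.85,636.1
Cnidaria,529,636.1
Bilateria,552.85,636.1
Deuterostomia,515.5,636.1
Chordata,514,636.1
Olfactores,514,636.1
Vertebrata,457.5,636.1
Gnathostomata,420.7,468.4
Osteichthyes,420.7,453.7
Tetrapoda,337,351
Amniota,318,332.9
Mammalia,164.9,201.5
Euarchontoglires,61.6,164.6
Cyclostomata,358.5,636.1
Xenambulacraria,515.5,636.1
Ambulacraria,515.5,636.1
Hemichordata,504.5,636.1
Protostomia,552.85,636.1
Annelids_Molluscs,534,636.1
Capitellid_Polychete_leech,476.5,636.1
Mollusca,534,549
Bivalve_Gastropod,530,549
Gastropoda,470.2,549
Ecdysozoa,528.82,636.1
Nematoda_Arthropoda,528.82,636.1
Lobopodia,528.82,636.1
Euarthropoda,514,636.1
Mandibulata,514,531.22
Pancrustacea,514,531.22
Copepoda_Branchiopoda,499,531.22
Eumetabola,305.5,413.6
Pycnogonida_other_chelicerates,497.5,531.22
Acari_Arenacea,416,531.22
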