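(((Amphimedon_queenslandica,Oscarella_carmela),Sycon_ciliatum),(Trichoplax_adhaerens,(Hydra_magnipapillata,(Nematostella_vectensis,Acropora_digitifera))Cnidaria,(((Adineta_vaga,Flaccisagitta_enflata,((Schmidtea_mediterranea,Schistosoma_mansoni),(Membranipora_membranacea,((Lingula_anatina,Terebratalia_transversa),((Capitella_teleta,(Platynereis_dumerilii,Helobdella_robusta))Capitellid_Polychete_leech,(Octopus_vulgaris,Crassostrea_gigas,(Lottia_gigantea,Aplysia_californica)Gastropoda)Mollusca)Annelids_Molluscs)))),(Priapulus_caudatus,(Caenorhabditis_elegans,Trichinella_spiralis),((Peripatopsis_capensis,Hypsibius_dujardini),((Endeis_spinosa,(Limulus_polyphemus,(Ixodes_scapularis,Parasteatoda_tepidariorum)Acari_Arenacea))Pycnogonida_other_chelicerates,(Strigamia_maritima,((Tigriopus_californicus,Daphnia_pulex)Copepoda_Branchiopoda,(Acyrthosiphon_pisum,(Drosophila_melanogaster,Tribolium_castaneum))Eumetabola)Pancrustacea)Mandibulata)Euarthropoda)Lobopodia)Ecdysozoa)Protostomia,((Branchiostoma_floridae,((Ciona_intestinalis,Halocynthia_roretzi),((Petromyzon_marinus,Eptatretus_burgeri)Cyclostomata,(Callorhinchus_milii,(Danio_rerio,(Latimeria_chalumnae,(Xenopus_tropicalis,((Anolis_carolinensis,Gallus_gallus),(Ornithorhynchus_anatinus,(Mus_musculus,Homo_sapiens)Euarchontoglires)Mammalia)Amniota)Tetrapoda))Osteichthyes)Gnathostomata)Vertebrata)Olfactores)Chordata,Xenoturbella_bocki,(Strongylocentrotus_purpuratus,(Saccoglossus_kowalevskii,Ptychodera_flava)Hemichordata)Ambulacraria)Deuterostomia)Bilateria)uncertain_E)Metazoa;
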