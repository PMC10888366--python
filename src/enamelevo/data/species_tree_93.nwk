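((Camelus_bactrianus:1.0,Vicugna_pacos:1.0):30.0,((Sus_scrofa:1.0,Catagonus_wagneri:1.0):29.0,((Tragulus_javanicus:7.0,((Giraffa_camelopardalis:1.0,Okapia_johnstoni:1.0):5.0,((Moschus_moschiferus:2.0,(Elaphurus_davidianus:1.0,Odocoileus_virginianus:1.0):1.0):3.0,((((Bison_bison:1.0,Bos_mutus:1.0):1.0,Bubalus_bubalis:2.0):1.0,Capra_hircus:3.0):1.0,Ovis_aries:4.0):1.0):1.0):1.0):22.0,((Choeropsis_liberiensis:1.0,Hippopotamus_amphibius:1.0):27.0,(((Balaena_mysticetus:3.0,((Eubalaena_australis:1.0,Eubalaena_glacialis:1.0):1.0,Eubalaena_japonica:2.0):1.0):6.0,(Caperea_marginata:8.0,(Eschrichtius_robustus:7.0,((((((Balaenoptera_acutorostrata:1.0,Balaenoptera_bonaerensis:1.0):1.0,Balaenoptera_borealis:2.0):1.0,Balaenoptera_musculus:3.0):1.0,Balaenoptera_physalus:4.0):1.0,Balaenoptera_ricei:5.0):1.0,Megaptera_novaeangliae:6.0):1.0):1.0):1.0):18.0,((Physeter_macrocephalus:2.0,(Kogia_breviceps:1.0,Kogia_sima:1.0):1.0):24.0,(((((((Berardius_arnuxii:1.0,Berardius_bairdii:1.0):1.0,(Hyperoodon_ampullatus:1.0,Hyperoodon_planifrons:1.0):1.0):1.0,Indopacetus_pacificus:3.0):9.0,(((((((((((Mesoplodon_bidens:1.0,Mesoplodon_bowdoini:1.0):1.0,Mesoplodon_carlhubbsi:2.0):1.0,Mesoplodon_densirostris:3.0):1.0,Mesoplodon_europaeus:4.0):1.0,Mesoplodon_ginkgodens:5.0):1.0,Mesoplodon_grayi:6.0):1.0,Mesoplodon_layardii:7.0):1.0,Mesoplodon_mirus:8.0):1.0,Mesoplodon_perrini:9.0):1.0,Mesoplodon_peruvianus:10.0):1.0,Mesoplodon_stejnegeri:11.0):1.0):1.0,Tasmacetus_shepherdi:13.0):1.0,Ziphius_cavirostris:14.0):11.0,((Platanista_gangetica:1.0,Platanista_minor:1.0):23.0,(Lipotes_vexillifer:23.0,((Inia_geoffrensis:1.0,Pontoporia_blainvillei:1.0):21.0,(((Delphinapterus_leucas:1.0,Monodon_monoceros:1.0):2.0,(Neophocaena_asiaeorientalis:2.0,(Phocoena_phocoena:1.0,Phocoena_sinus:1.0):1.0):1.0):18.0,((((((((((((((((((((Cephalorhynchus_commersonii:1.0,Cephalorhynchus_eutropia:1.0):1.0,Cephalorhynchus_heavisidii:2.0):1.0,Cephalorhynchus_hectori:3.0):1.0,(Delphinus_delphis_bairdii:1.0,Delphinus_delphis_delphis:1.0):3.0):1.0,Feresa_attenuata:5.0):1.0,(Globicephala_macrorhynchus:1.0,Globicephala_melas:1.0):5.0):1.0,Grampus_griseus:7.0):1.0,Lagenodelphis_hosei:8.0):1.0,Lagenorhynchus_albirostris:9.0):1.0,Leucopleurus_acutus:10.0):1.0,(Lissodelphis_borealis:1.0,Lissodelphis_peronii:1.0):10.0):1.0,(Orcaella_brevirostris:1.0,Orcaella_heinsohni:1.0):11.0):1.0,Orcinus_orca:13.0):1.0,Peponocephala_electra:14.0):1.0,Pseudorca_crassidens:15.0):1.0,(Sagmatias_obliquidens:1.0,Sagmatias_obscurus:1.0):15.0):1.0,Sousa_chinensis:17.0):1.0,((((Stenella_attenuata:1.0,Stenella_clymene:1.0):1.0,Stenella_coeruleoalba:2.0):1.0,Stenella_frontalis:3.0):1.0,Stenella_longirostris:4.0):14.0):1.0,Steno_bredanensis:19.0):1.0,(Tursiops_aduncus:1.0,Tursiops_truncatus:1.0):19.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0);
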