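taxon	group	family
Cephalorhynchus_commersonii	Odontoceti	Delphinidae
Cephalorhynchus_eutropia	Odontoceti	Delphinidae
Cephalorhynchus_heavisidii	Odontoceti	Delphinidae
Cephalorhynchus_hectori	Odontoceti	Delphinidae
Delphinus_delphis_bairdii	Odontoceti	Delphinidae
Delphinus_delphis_delphis	Odontoceti	Delphinidae
Feresa_attenuata	Odontoceti	Delphinidae
Globicephala_macrorhynchus	Odontoceti	Delphinidae
Globicephala_melas	Odontoceti	Delphinidae
Grampus_griseus	Odontoceti	Delphinidae
Lagenodelphis_hosei	Odontoceti	Delphinidae
Lagenorhynchus_albirostris	Odontoceti	Delphinidae
Leucopleurus_acutus	Odontoceti	Delphinidae
Lissodelphis_borealis	Odontoceti	Delphinidae
Lissodelphis_peronii	Odontoceti	Delphinidae
Orcaella_brevirostris	Odontoceti	Delphinidae
Orcaella_heinsohni	Odontoceti	Delphinidae
Orcinus_orca	Odontoceti	Delphinidae
Peponocephala_electra	Odontoceti	Delphinidae
Pseudorca_crassidens	Odontoceti	Delphinidae
Sagmatias_obliquidens	Odontoceti	Delphinidae
Sagmatias_obscurus	Odontoceti	Delphinidae
Sousa_chinensis	Odontoceti	Delphinidae
Stenella_attenuata	Odontoceti	Delphinidae
Stenella_clymene	Odontoceti	Delphinidae
Stenella_coeruleoalba	Odontoceti	Delphinidae
Stenella_frontalis	Odontoceti	Delphinidae
Stenella_longirostris	Odontoceti	Delphinidae
Steno_bredanensis	Odontoceti	Delphinidae
Tursiops_aduncus	Odontoceti	Delphinidae
Tursiops_truncatus	Odontoceti	Delphinidae
Inia_geoffrensis	Odontoceti	Iniidae
Kogia_breviceps	Odontoceti	Kogiidae
Kogia_sima	Odontoceti	Kogiidae
Lipotes_vexillifer	Odontoceti	Lipotidae
Delphinapterus_leucas	Odontoceti	Monodontidae
Monodon_monoceros	Odontoceti	Monodontidae
Neophocaena_asiaeorientalis	Odontoceti	Phocoenidae
Phocoena_phocoena	Odontoceti	Phocoenidae
Phocoena_sinus	Odontoceti	Phocoenidae
Physeter_macrocephalus	Odontoceti	Physeteridae
Platanista_gangetica	Odontoceti	Platanistidae
Platanista_minor	Odontoceti	Platanistidae
Pontoporia_blainvillei	Odontoceti	Pontoporiidae
Berardius_arnuxii	Odontoceti	Ziphiidae
Berardius_bairdii	Odontoceti	Ziphiidae
Hyperoodon_ampullatus	Odontoceti	Ziphiidae
Hyperoodon_planifrons	Odontoceti	Ziphiidae
Indopacetus_pacificus	Odontoceti	Ziphiidae
Mesoplodon_bidens	Odontoceti	Ziphiidae
Mesoplodon_bowdoini	Odontoceti	Ziphiidae
Mesoplodon_carlhubbsi	Odontoceti	Ziphiidae
Mesoplodon_densirostris	Odontoceti	Ziphiidae
Mesoplodon_europaeus	Odontoceti	Ziphiidae
Mesoplodon_ginkgodens	Odontoceti	Ziphiidae
Mesoplodon_grayi	Odontoceti	Ziphiidae
Mesoplodon_layardii	Odontoceti	Ziphiidae
Mesoplodon_mirus	Odontoceti	Ziphiidae
Mesoplodon_perrini	Odontoceti	Ziphiidae
Mesoplodon_peruvianus	Odontoceti	Ziphiidae
Mesoplodon_stejnegeri	Odontoceti	Ziphiidae
Tasmacetus_shepherdi	Odontoceti	Ziphiidae
Ziphius_cavirostris	Odontoceti	Ziphiidae
Balaena_mysticetus	Mysticeti	Balaenidae
Eubalaena_australis	Mysticeti	Balaenidae
Eubalaena_glacialis	Mysticeti	Balaenidae
Eubalaena_japonica	Mysticeti	Balaenidae
Balaenoptera_acutorostrata	Mysticeti	Balaenopteridae
Balaenoptera_bonaerensis	Mysticeti	Balaenopteridae
Balaenoptera_borealis	Mysticeti	Balaenopteridae
Balaenoptera_musculus	Mysticeti	Balaenopteridae
Balaenoptera_physalus	Mysticeti	Balaenopteridae
Balaenoptera_ricei	Mysticeti	Balaenopteridae
Megaptera_novaeangliae	Mysticeti	Balaenopteridae
Eschrichtius_robustus	Mysticeti	Eschrichtiidae
Caperea_marginata	Mysticeti	Neobalaenidae
Bison_bison	Outgroup	Bovidae
Bos_mutus	Outgroup	Bovidae
Bubalus_bubalis	Outgroup	Bovidae
Capra_hircus	Outgroup	Bovidae
Ovis_aries	Outgroup	Bovidae
Camelus_bactrianus	Outgroup	Camelidae
Vicugna_pacos	Outgroup	Camelidae
Elaphurus_davidianus	Outgroup	Cervidae
Odocoileus_virginianus	Outgroup	Cervidae
Giraffa_camelopardalis	Outgroup	Giraffidae
Okapia_johnstoni	Outgroup	Giraffidae
Choeropsis_liberiensis	Outgroup	Hippopotamidae
Hippopotamus_amphibius	Outgroup	Hippopotamidae
Moschus_moschiferus	Outgroup	Moschidae
Sus_scrofa	Outgroup	Suidae
Catagonus_wagneri	Outgroup	Tayassuidae
Tragulus_javanicus	Outgroup	Tragulidae
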