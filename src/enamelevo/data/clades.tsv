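clade	members
Balaenidae	Balaena_mysticetus;Eubalaena_australis;Eubalaena_glacialis;Eubalaena_japonica
Balaenoptera	Balaenoptera_acutorostrata;Balaenoptera_bonaerensis;Balaenoptera_borealis;Balaenoptera_musculus;Balaenoptera_physalus;Balaenoptera_ricei
Balaenopteridae	Balaenoptera_acutorostrata;Balaenoptera_bonaerensis;Balaenoptera_borealis;Balaenoptera_musculus;Balaenoptera_physalus;Balaenoptera_ricei;Megaptera_novaeangliae
Berardius	Berardius_arnuxii;Berardius_bairdii
Bovidae	Bison_bison;Bos_mutus;Bubalus_bubalis;Capra_hircus;Ovis_aries
Camelidae	Camelus_bactrianus;Vicugna_pacos
Cephalorhynchus	Cephalorhynchus_commersonii;Cephalorhynchus_eutropia;Cephalorhynchus_heavisidii;Cephalorhynchus_hectori
Cervidae	Elaphurus_davidianus;Odocoileus_virginianus
Delphinidae	Cephalorhynchus_commersonii;Cephalorhynchus_eutropia;Cephalorhynchus_heavisidii;Cephalorhynchus_hectori;Delphinus_delphis_bairdii;Delphinus_delphis_delphis;Feresa_attenuata;Globicephala_macrorhynchus;Globicephala_melas;Grampus_griseus;Lagenodelphis_hosei;Lagenorhynchus_albirostris;Leucopleurus_acutus;Lissodelphis_borealis;Lissodelphis_peronii;Orcaella_brevirostris;Orcaella_heinsohni;Orcinus_orca;Peponocephala_electra;Pseudorca_crassidens;Sagmatias_obliquidens;Sagmatias_obscurus;Sousa_chinensis;Stenella_attenuata;Stenella_clymene;Stenella_coeruleoalba;Stenella_frontalis;Stenella_longirostris;Steno_bredanensis;Tursiops_aduncus;Tursiops_truncatus
Delphinus	Delphinus_delphis_bairdii;Delphinus_delphis_delphis
Eschrichtiidae	Eschrichtius_robustus
Eubalaena	Eubalaena_australis;Eubalaena_glacialis;Eubalaena_japonica
Giraffidae	Giraffa_camelopardalis;Okapia_johnstoni
Globicephala	Globicephala_macrorhynchus;Globicephala_melas
Hippopotamidae	Choeropsis_liberiensis;Hippopotamus_amphibius
Hyperoodon	Hyperoodon_ampullatus;Hyperoodon_planifrons
Iniidae	Inia_geoffrensis
Inioidea	Inia_geoffrensis;Pontoporia_blainvillei
Kogia	Kogia_breviceps;Kogia_sima
Kogiidae	Kogia_breviceps;Kogia_sima
Lipotidae	Lipotes_vexillifer
Lissodelphis	Lissodelphis_borealis;Lissodelphis_peronii
Mesoplodon	Mesoplodon_bidens;Mesoplodon_bowdoini;Mesoplodon_carlhubbsi;Mesoplodon_densirostris;Mesoplodon_europaeus;Mesoplodon_ginkgodens;Mesoplodon_grayi;Mesoplodon_layardii;Mesoplodon_mirus;Mesoplodon_perrini;Mesoplodon_peruvianus;Mesoplodon_stejnegeri
Monodontidae	Delphinapterus_leucas;Monodon_monoceros
Moschidae	Moschus_moschiferus
Mysticeti	Balaena_mysticetus;Balaenoptera_acutorostrata;Balaenoptera_bonaerensis;Balaenoptera_borealis;Balaenoptera_musculus;Balaenoptera_physalus;Balaenoptera_ricei;Caperea_marginata;Eschrichtius_robustus;Eubalaena_australis;Eubalaena_glacialis;Eubalaena_japonica;Megaptera_novaeangliae
Neobalaenidae	Caperea_marginata
Odontoceti	Berardius_arnuxii;Berardius_bairdii;Cephalorhynchus_commersonii;Cephalorhynchus_eutropia;Cephalorhynchus_heavisidii;Cephalorhynchus_hectori;Delphinapterus_leucas;Delphinus_delphis_bairdii;Delphinus_delphis_delphis;Feresa_attenuata;Globicephala_macrorhynchus;Globicephala_melas;Grampus_griseus;Hyperoodon_ampullatus;Hyperoodon_planifrons;Indopacetus_pacificus;Inia_geoffrensis;Kogia_breviceps;Kogia_sima;Lagenodelphis_hosei;Lagenorhynchus_albirostris;Leucopleurus_acutus;Lipotes_vexillifer;Lissodelphis_borealis;Lissodelphis_peronii;Mesoplodon_bidens;Mesoplodon_bowdoini;Mesoplodon_carlhubbsi;Mesoplodon_densirostris;Mesoplodon_europaeus;Mesoplodon_ginkgodens;Mesoplodon_grayi;Mesoplodon_layardii;Mesoplodon_mirus;Mesoplodon_perrini;Mesoplodon_peruvianus;Mesoplodon_stejnegeri;Monodon_monoceros;Neophocaena_asiaeorientalis;Orcaella_brevirostris;Orcaella_heinsohni;Orcinus_orca;Peponocephala_electra;Phocoena_phocoena;Phocoena_sinus;Physeter_macrocephalus;Platanista_gangetica;Platanista_minor;Pontoporia_blainvillei;Pseudorca_crassidens;Sagmatias_obliquidens;Sagmatias_obscurus;Sousa_chinensis;Stenella_attenuata;Stenella_clymene;Stenella_coeruleoalba;Stenella_frontalis;Stenella_longirostris;Steno_bredanensis;Tasmacetus_shepherdi;Tursiops_aduncus;Tursiops_truncatus;Ziphius_cavirostris
Orcaella	Orcaella_brevirostris;Orcaella_heinsohni
Phocoena	Phocoena_phocoena;Phocoena_sinus
Phocoenidae	Neophocaena_asiaeorientalis;Phocoena_phocoena;Phocoena_sinus
Physeteridae	Physeter_macrocephalus
Physeteroidea	Kogia_breviceps;Kogia_sima;Physeter_macrocephalus
Platanista	Platanista_gangetica;Platanista_minor
Platanistidae	Platanista_gangetica;Platanista_minor
Pontoporiidae	Pontoporia_blainvillei
Sagmatias	Sagmatias_obliquidens;Sagmatias_obscurus
Stenella	Stenella_attenuata;Stenella_clymene;Stenella_coeruleoalba;Stenella_frontalis;Stenella_longirostris
Suidae	Sus_scrofa
Tayassuidae	Catagonus_wagneri
Tragulidae	Tragulus_javanicus
Tursiops	Tursiops_aduncus;Tursiops_truncatus
Ziphiidae	Berardius_arnuxii;Berardius_bairdii;Hyperoodon_ampullatus;Hyperoodon_planifrons;Indopacetus_pacificus;Mesoplodon_bidens;Mesoplodon_bowdoini;Mesoplodon_carlhubbsi;Mesoplodon_densirostris;Mesoplodon_europaeus;Mesoplodon_ginkgodens;Mesoplodon_grayi;Mesoplodon_layardii;Mesoplodon_mirus;Mesoplodon_perrini;Mesoplodon_peruvianus;Mesoplodon_stejnegeri;Tasmacetus_shepherdi;Ziphius_cavirostris
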