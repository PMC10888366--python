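(Camelus_bactrianus:23.0,(Sus_scrofa:22.0,(Bos_mutus:21.0,(Hippopotamus_amphibius:20.0,((Physeter_macrocephalus:2.0,(Kogia_breviceps:1.0,Kogia_sima:1.0):1.0):17.0,(((Berardius_bairdii:1.0,Mesoplodon_densirostris:1.0):1.0,Ziphius_cavirostris:2.0):16.0,((Platanista_gangetica:1.0,Platanista_minor:1.0):16.0,((Inia_geoffrensis:1.0,Pontoporia_blainvillei:1.0):15.0,(((Delphinapterus_leucas:1.0,Monodon_monoceros:1.0):1.0,(Neophocaena_asiaeorientalis:1.0,Phocoena_phocoena:1.0):1.0):13.0,(((((((((((((Cephalorhynchus_hectori:2.0,(Delphinus_delphis_bairdii:1.0,Delphinus_delphis_delphis:1.0):1.0):1.0,(Globicephala_macrorhynchus:1.0,Globicephala_melas:1.0):2.0):1.0,Grampus_griseus:4.0):1.0,Lagenodelphis_hosei:5.0):1.0,Lagenorhynchus_albirostris:6.0):1.0,Leucopleurus_acutus:7.0):1.0,Orcaella_brevirostris:8.0):1.0,Orcinus_orca:9.0):1.0,Pseudorca_crassidens:10.0):1.0,Sagmatias_obscurus:11.0):1.0,(((Stenella_attenuata:1.0,Stenella_clymene:1.0):1.0,Stenella_coeruleoalba:2.0):1.0,Stenella_frontalis:3.0):9.0):1.0,Steno_bredanensis:13.0):1.0,Tursiops_truncatus:14.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0);
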