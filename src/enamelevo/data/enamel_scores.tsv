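taxon	score
Berardius_bairdii	2
Cephalorhynchus_hectori	4
Delphinapterus_leucas	2/3
Delphinus_delphis_bairdii	4
Delphinus_delphis_delphis	4
Globicephala_macrorhynchus	4
Globicephala_melas	4
Grampus_griseus	4
Inia_geoffrensis	5
Kogia_breviceps	2
Kogia_sima	2
Lagenodelphis_hosei	4
Leucopleurus_acutus	4
Lagenorhynchus_albirostris	4
Sagmatias_obscurus	4
Mesoplodon_densirostris	1/2
Monodon_monoceros	1
Neophocaena_asiaeorientalis	3
Orcaella_brevirostris	4
Orcinus_orca	4
Phocoena_phocoena	3
Physeter_macrocephalus	1/2
Platanista_gangetica	5
Platanista_minor	5
Pontoporia_blainvillei	4
Pseudorca_crassidens	4
Stenella_attenuata	4
Stenella_clymene	4
Stenella_coeruleoalba	4
Stenella_frontalis	4
Steno_bredanensis	4
Tursiops_truncatus	4
Ziphius_cavirostris	1
Bos_mutus	5
Camelus_bactrianus	5
Hippopotamus_amphibius	5
Sus_scrofa	5
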