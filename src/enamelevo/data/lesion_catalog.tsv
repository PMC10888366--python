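bearer	notation
Kogiidae	*ACP4*: E1-3, 11: NBR/NRM; *AMELX*: E2: 47I; In2Do: GG; *ENAM*: E8: 2403D; E8: 3751-3752D; *KLK4*: WGD (NBR/NRM)
Phocoenidae	*AMTN*: In2Ac: AT; *KLK4*: E2: 73-75S
Platanista	*AMTN*: E3: NBR
Hyperoodon	*AMTN*: E8: 566D
Monodontidae	*AMELX*: In2Do: AT
Berardius_arnuxii	*AMELX*: E7: NBR/NRM; *ENAM*: E8: 648I
Berardius_bairdii	*MMP20*: E5: 1095-1097S
Delphinapterus_leucas	*ACP4*: E7: 674D; *AMTN*: E8: 576D
Hyperoodon_ampullatus	*ENAM*: In6Do: TT
Hyperoodon_planifrons	*AMELX*: E7: NBR/NRM
Kogia_breviceps	*ACP4*: E9: 900D; E10: 1100I; *AMBN*: In7Ac: AT; In9Ac: AT; *AMELX*: E2: SCM; *AMTN*: E8: 377D; *ENAM*: In6Do: CT
Kogia_sima	*AMBN*: WGD (NBR/NRM); *ENAM*: E1-6: NBR/NRM
Mesoplodon_bidens	*ACP4*: E2: 145-148I; E5: 537-544D; In8Ac: GG
Mesoplodon_densirostris	*ACP4*: E5: 537-539S (allelic variation); *AMTN*: E5: 249-252I (allelic variation)
Mesoplodon_grayi	*ACP4*: E8: 802I (allelic variation); *AMELX*: In2Ac: GG/AG (allelic variation)
Mesoplodon_layardii	*KLK4*: In2Do: CG/GT (allelic variation)
Mesoplodon_perrini	*AMTN*: E8-9: NRM (no stop)
Mesoplodon_peruvianus	*AMELX*: E7: NBR/NRM; *AMTN*: E8: 376I
Monodon_monoceros	*ACP4*: In6Do: AT; *AMBN*: E11: 1214-1216S; *KLK4*: E4: 503-505S
Orcinus_orca	*ENAM*: In4Do: AT/GT (allelic variation)
Physeter_macrocephalus	*ACP4*: E4: 427D; E9: 1015D; E10: 1132D (allelic variation)
Tasmacetus_shepherdi	*KLK4*: E5: 767-769TCM
Ziphius_cavirostris	*KLK4*: In3Ac: GG
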