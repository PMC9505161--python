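(((Cycas_revoluta:0.12,Zamia_furfuracea:0.14):0.08,Ginkgo_biloba:0.20):0.06,(((Cedrus_deodara:0.11,(Abies_firma:0.09,(Picea_smithiana:0.07,Pinus_armandii:0.08):0.04):0.03):0.10,(Ephedra_przewalskii:0.28,(Welwitschia_mirabilis:0.25,Gnetum_montanum:0.24):0.09):0.16):0.05,(Sciadopitys_verticillata:0.18,((Podocarpus_macrophyllus:0.16,Araucaria_cunninghamii:0.14):0.05,((Cephalotaxus_sinensis:0.10,Taxus_cuspidata:0.11):0.05,(Cunninghamia_lanceolata:0.09,(Taiwania_cryptomerioides:0.08,(Metasequoia_glyptostroboides:0.07,Platycladus_orientalis:0.08):0.03):0.03):0.06):0.04):0.04):0.07):0.06);
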