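species	type	total	codon1	codon2	codon3	silent	nonsynonymous	tRNA	rRNA	intron	intergenic
Cycas revoluta	C-to-U	152	23	89	11	13	110	0	0	7	22
Cycas revoluta	G-to-A	6	1	1	0	0	2	0	2	1	1
Zamia furfuracea	C-to-U	265	36	111	42	41	148	0	0	20	56
Zamia furfuracea	G-to-A	10	3	3	0	0	6	0	2	1	1
Ginkgo biloba	C-to-U	304	53	157	27	27	210	0	0	23	44
Ginkgo biloba	G-to-A	3	0	0	0	0	0	0	2	0	1
Cedrus deodara	C-to-U	95	15	67	3	3	82	0	0	9	1
Cedrus deodara	G-to-A	1	0	0	0	0	0	0	1	0	0
Abies firma	C-to-U	77	10	51	5	5	61	0	1	8	2
Abies firma	G-to-A	4	0	0	1	1	0	0	1	1	1
Picea smithiana	C-to-U	161	23	84	12	12	107	0	1	14	27
Picea smithiana	G-to-A	4	1	0	2	2	1	0	1	0	0
Pinus armandii	C-to-U	49	7	28	5	6	34	0	0	4	5
Pinus armandii	G-to-A	5	0	1	0	0	1	0	0	0	4
Ephedra przewalskii	C-to-U	1	0	1	0	0	1	0	0	0	0
Ephedra przewalskii	G-to-A	2	0	0	1	1	0	0	0	0	1
Welwitschia mirabilis	C-to-U	2	1	0	1	1	1	0	0	0	0
Welwitschia mirabilis	G-to-A	4	1	0	1	1	1	0	2	0	0
Gnetum montanum	C-to-U	3	0	3	0	0	3	0	0	0	0
Gnetum montanum	G-to-A	4	0	0	0	0	0	0	2	1	1
Podocarpus macrophyllus	C-to-U	20	2	17	0	0	19	0	0	0	1
Podocarpus macrophyllus	G-to-A	4	0	0	1	1	0	0	0	1	2
Araucaria cunninghamii	C-to-U	45	4	32	3	5	34	0	0	1	5
Araucaria cunninghamii	G-to-A	1	0	0	0	0	0	0	1	0	0
Sciadopitys verticillata	C-to-U	41	7	20	5	5	27	0	0	4	5
Sciadopitys verticillata	G-to-A	5	2	0	0	0	2	0	1	0	2
Cephalotaxus sinensis	C-to-U	40	6	25	1	1	31	0	1	3	4
Cephalotaxus sinensis	G-to-A	6	0	0	1	0	1	0	1	0	4
Taxus cuspidata	C-to-U	25	1	19	2	2	20	0	0	0	3
Taxus cuspidata	G-to-A	2	0	1	0	0	1	0	1	0	0
Cunninghamia lanceolata	C-to-U	18	3	14	0	0	17	0	0	1	0
Cunninghamia lanceolata	G-to-A	2	0	0	0	0	0	0	1	1	0
Taiwania cryptomerioides	C-to-U	18	2	14	1	1	16	0	0	0	1
Taiwania cryptomerioides	G-to-A	2	0	0	0	0	0	1	1	0	0
Metasequoia glyptostroboides	C-to-U	24	4	14	3	4	17	0	0	0	3
Metasequoia glyptostroboides	G-to-A	4	0	0	1	1	0	0	1	1	1
Platycladus orientalis	C-to-U	24	5	13	0	1	17	0	0	1	5
Platycladus orientalis	G-to-A	2	1	0	0	0	1	0	1	0	0
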