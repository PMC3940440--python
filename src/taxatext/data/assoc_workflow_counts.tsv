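# Association-workflow confusion counts per test species (reference evaluation).
unit	tp	fp	fn	tn
Carcharodon carcharias	9	2	2	23
Panthera leo	30	2	4	16
Hypnum fauriei	0	0	0	1
Pseudo-nitzschia australis	0	0	0	3
Culex pipiens	0	0	0	6
Escherichia coli	0	0	1	119
Harrisia simpsonii	1	0	0	5
Quercus robur	81	2	3	15
Lumbricus terrestris	0	0	2	3
Callinectes sapidus	49	9	11	13
Loxosceles reclusa	0	0	0	11
Paramecium aurelia	0	0	0	1
Psilocybe cubensis	0	0	0	51
Oryctes nasicornis	0	0	1	24
Odobenus rosmarus	1	1	1	17
Hypsibius dujardini	0	0	0	7
Tobacco mosaic virus	5	0	1	0
Eurytemora affinis	0	0	0	4
Nereocystis luetkeana	0	0	0	2
Riftia pachyptila	0	0	0	7
Apis mellifera	318	75	17	19
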