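# Baseline (name finder alone, no workflow) confusion counts per test species.
unit	tp	fp	fn	tn
Carcharodon carcharias	10	37	1	0
Panthera leo	33	45	2	0
Hypnum fauriei	0	2	0	0
Pseudo-nitzschia australis	0	7	0	0
Culex pipiens	0	7	0	0
Escherichia coli	0	135	1	0
Harrisia simpsonii	1	7	0	0
Quercus robur	82	26	2	3
Lumbricus terrestris	2	4	0	0
Callinectes sapidus	53	28	2	1
Loxosceles reclusa	0	16	0	0
Paramecium aurelia	0	3	0	0
Psilocybe cubensis	0	55	0	1
Oryctes nasicornis	1	25	0	0
Odobenus rosmarus	2	29	0	1
Hypsibius dujardini	0	8	0	0
Tobacco mosaic virus	5	3	1	0
Eurytemora affinis	0	6	0	0
Nereocystis luetkeana	0	4	0	0
Riftia pachyptila	0	12	0	0
Apis mellifera	321	101	15	0
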