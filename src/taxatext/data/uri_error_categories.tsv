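# Manually categorized URI annotation errors per test species (reference
# evaluation). The moss received no annotations and hence no errors; its
# all-N/A row is omitted.
unit	negation	related_taxa	word_part	generality	homonym
Carcharodon carcharias	2	7	1	2	0
Panthera leo	0	4	2	0	0
Pseudo-nitzschia australis	0	1	1	2	0
Culex pipiens	0	0	0	0	0
Escherichia coli	0	1	1	3	1
Harrisia simpsonii	0	0	0	0	0
Quercus robur	0	2	0	0	0
Lumbricus terrestris	0	1	0	1	1
Callinectes sapidus	0	3	0	0	1
Loxosceles reclusa	0	1	0	0	2
Paramecium aurelia	0	0	0	0	0
Psilocybe cubensis	0	0	0	1	0
Oryctes nasicornis	0	0	0	0	0
Odobenus rosmarus	1	0	2	1	3
Hypsibius dujardini	0	0	0	0	1
Eurytemora affinis	0	0	0	0	0
Tobacco mosaic virus	0	0	0	0	0
Nereocystis luetkeana	0	0	1	0	0
Riftia pachyptila	1	1	1	0	1
Apis mellifera	0	0	2	0	1
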