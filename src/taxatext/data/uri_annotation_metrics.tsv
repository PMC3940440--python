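# Per-species URI annotation results (reference evaluation): object counts,
# correct URI tallies and printed precision/recall.
unit	n_objects	n_correct_uris	n_unique_uris	precision	recall
Carcharodon carcharias	56	169	45	0.918	1
Panthera leo	52	173	45	0.961	1
Hypnum fauriei	2	0	0	0	0
Pseudo-nitzschia australis	19	23	14	0.852	1
Culex pipiens	8	8	6	1	1
Escherichia coli	7	36	17	0.783	1
Harrisia simpsonii	20	13	9	1	1
Quercus robur	36	37	20	0.949	1
Lumbricus terrestris	17	28	15	0.903	1
Callinectes sapidus	45	94	36	0.95	1
Loxosceles reclusa	17	27	16	0.871	1
Paramecium aurelia	2	3	3	1	1
Psilocybe cubensis	9	9	7	0.9	1
Oryctes nasicornis	2	5	5	1	1
Odobenus rosmarus	57	100	35	0.909	1
Hypsibius dujardini	4	5	5	0.833	1
Tobacco mosaic virus	2	5	4	1	1
Eurytemora affinis	6	6	4	1	1
Nereocystis luetkeana	9	7	5	0.875	1
Riftia pachyptila	55	68	17	0.523	1
Apis mellifera	61	222	54	0.978	1
GRAND TOTAL	487	1038	362	0.889	1
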