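# taxatext

Offline toolkit for two text-mining workflows over taxon-page text, as used
by biodiversity aggregators such as the Encyclopedia of Life (EOL), where
each species page carries narrative "text objects" filed under topical
subchapters:

1. **Semantic URI annotation.** Each text object is tagged with concept URIs
   (e.g. DBpedia resources) by lowercase substring search of *stem keys* —
   deliberately truncated dictionary entries such as `predat` that match
   predator, predation and predatory with one key.
2. **Species association network extraction.** Scientific names are located
   in the prose of the four ecology subchapters (Associations, Trophic
   Strategy, General Ecology, Habitat), reconciled against a names authority
   (synonyms mapped to accepted names and taxon ids), and turned into a
   directed graph: *page subject → mentioned taxon*, read as an ecological
   association.

The package also ships the complete evaluation harness used to judge both
workflows — confusion counts, precision/recall/F1 (per unit and
micro-averaged), Fleiss' kappa for inter-annotator agreement, relative
improvement over a baseline, and error-category reporting for the five
documented false-positive classes (negation, describing related taxa, word
part, generalities, homonym) — plus a seeded synthetic-corpus generator
that plants gold annotations, gold associations and trap sentences at
configurable rates, so the whole pipeline is testable with no network
access.

## Definitions

For a unit with true/false positives and false negatives (TP, FP, FN):

    precision P = TP / (TP + FP)
    recall    R = TP / (TP + FN)
    F1          = 2PR / (P + R)        (harmonic mean, unrounded P and R)

0/0 ratios evaluate to 0 by convention. Micro-averaged totals come from
summed counts. Agreement between n raters assigning items to categories is
Fleiss' κ = (P̄ − P̄e)/(1 − P̄e).

## Worked example

Generate a synthetic corpus (6 taxa, default study-like error rates), tag
it, and score it against its own gold standard:

    taxatext simulate --seed 7 --n-taxa 6 --out sim
    taxatext annotate --corpus sim/corpus.json --dictionary sim/dictionary.tsv --out ann
    taxatext evaluate-annotations --annotations ann/annotations.tsv \
        --gold sim/gold_annotations.tsv --out eval

which logs

    wrote 12 taxa / 84 objects to sim
    204 hits over 84 units (8% received none); mean 2.43 hits and 2.43 unique URIs per unit
    micro: tp=182 fp=22 fn=0

and writes a per-object metrics table ending in

    TOTAL   182  22   0   0     0.892  1.000  0.943

Recall is 1 because every planted stem is a verbatim substring — finding
strings is the easy part. Precision is below 1 exactly because of the 22
planted trap sentences, and `eval/error_categories.tsv` confirms every one
fired, by category:

    category        planted fired
    negation        1       1
    related_taxa    10      10
    word_part       4       4
    generality      4       4
    homonym         3       3
    TOTAL           22      22

The network half of the pipeline:

    taxatext build-network --corpus sim/corpus.json --names sim/names.tsv --out net
    taxatext evaluate-network --network net/network.tsv \
        --gold sim/gold_associations.tsv --corpus sim/corpus.json \
        --names sim/names.tsv --out neteval

    network: 6 nodes, 27 edges
    tp=27 fp=0 fn=0 tn=0

With traps off and strict name finding, extraction against planted gold is
exact. Self-mentions are filtered by default; an optional higher-taxon
filter drops edges to a genus when one of its species is resolved on the
same page (the dominant false-positive class in this kind of extraction).

All of this is equally usable as a library — see `taxatext.annotator`,
`taxatext.network`, `taxatext.evaluation` — and every run writes a
`manifest.json` (seed, config, input checksums) so outputs are reproducible
byte for byte.

## Layout

    src/taxatext/
      corpus.py      data model, markup cleaning, subchapter filtering
      dictionary.py  stem-key → URI dictionary, loading and linting
      annotator.py   substring annotation, object- and taxon-scope
      name_finder.py binomial grammar, abbreviation expansion, table-exact names
      resolver.py    names authority and synonym resolution
      network.py     association extraction, filters, TSV/SIF/GraphML export
      evaluation.py  confusion counts, P/R/F1, Fleiss' kappa, reports, gold I/O
      synthdata.py   seeded synthetic corpora with planted gold and traps
      refdata.py     packaged reference tables
      cli.py         `taxatext` command-line interface
    docs/methods.md  models, parameters, design choices, limitations
    docs/formats.md  all on-disk file formats
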