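# On-disk formats

All files are UTF-8; all tables are tab-separated with a header row unless
noted. `#`-prefixed lines are comments where stated.

## Corpus bundle (`corpus.json`)

One JSON object with two arrays:

```json
{
  "taxa": [
    {"taxon_id": "T0001", "canonical_name": "Panthera leo",
     "rank": "species", "parent_id": "G001",
     "synonyms": ["Felis leo"], "common_names": ["lion"]}
  ],
  "objects": [
    {"object_id": "O00001", "taxon_id": "T0001",
     "subchapter": "TrophicStrategy", "body": "…",
     "language": "en", "trusted": true, "source": "provider name"}
  ]
}
```

`rank`, `parent_id`, `synonyms`, `common_names`, `language`, `trusted` and
`source` are optional (defaults: null/empty, "en", true, ""). Object ids
must be globally unique; every object's `taxon_id` must exist in `taxa`.
Bodies may contain HTML; they are cleaned at load. Subchapter labels match
space- and case-insensitively; the ecology set is Associations,
TrophicStrategy, GeneralEcology, Habitat.

## Dictionary (`dictionary.tsv`)

Two columns, no header: `key<TAB>uri`. Keys are lowercase stems, unique,
in significant order; URIs must be absolute. `#` comments allowed. A
tolerant importer also reads `'key': 'uri'` literal-style listings.

## Names table (`names.tsv`)

Columns: `name`, `accepted_name`, `taxon_id`, `status`, `rank`,
`parent_id` (last two optional/blank). `status` is `current` or `synonym`;
every synonym's `accepted_name` must have a current row. Names are matched
case-insensitively with whitespace normalized.

## Annotations (`annotations.tsv`)

Columns: `object_id`, `key`, `uri`, `offset` — one row per hit, offset
0-based into the lowercased body, rows sorted by object id.

## Gold annotations (`gold_annotations.tsv`)

Columns: `object_id`, `uri`, `error_category`. A blank category marks a
gold positive; a non-blank category (one of `negation`, `related_taxa`,
`word_part`, `generality`, `homonym`) marks an expected false positive —
a URI whose key occurs in the text but which a human would reject.

## Gold associations (`gold_associations.tsv`)

Columns: `subject_taxon_id`, `object_taxon_id`; unique directed pairs.

## Mentions (`mentions.tsv`)

Columns: `object_id`, `offset`, `verbatim`, `canonical`, `form`
(`binomial` | `uninomial` | `abbreviated-binomial` | `table-exact`).

## Network exports

- `network.tsv`: `subject_taxon_id`, `object_taxon_id`,
  `n_supporting_objects`; header always present; round-trips.
- `network.sif`: `subject<TAB>assoc<TAB>object`, one edge per line.
- `network.graphml`: GraphML with `n_supporting_objects` edge attribute;
  directed by default.

## Ratings (`ratings.tsv`)

An `item` column plus one integer column per category; each row sums to
the (constant) number of raters.

## Run manifest (`manifest.json`)

Written by every CLI subcommand: tool version, subcommand, effective
config, SHA-256 of each input, list of outputs. No timestamps, so
identical runs produce identical manifests.

## Packaged reference tables (`src/taxatext/data/`)

- `assoc_workflow_counts.tsv`, `assoc_baseline_counts.tsv`: `unit`, `tp`,
  `fp`, `fn`, `tn` per test species.
- `uri_error_categories.tsv`: `unit` plus one column per error category.
- `uri_annotation_metrics.tsv`: `unit`, `n_objects`, `n_correct_uris`,
  `n_unique_uris`, `precision`, `recall`.
- `workflow_summary.tsv`: `stat`, `value` corpus-level summary numbers.
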