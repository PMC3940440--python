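# Methods

## The two workflows

**URI annotation.** A dictionary maps lowercase *stem keys* to concept
URIs. Each text object's body is lowercased once and every key is searched
for as a contiguous substring; the first occurrence yields one hit and the
scan moves to the next key, so a result carries at most one hit per key.
Substring matching deliberately crosses word boundaries — that is what lets
`predat` cover predator/predation/predatory from a single entry, keeping
the dictionary small — and it is also the direct cause of the *word-part*
false-positive class (`forest` firing inside "kelp forest"). The annotator
does not attempt negation handling, word-sense disambiguation or context
windows: those error classes are measured by the evaluation module, not
prevented, because the method's value lies in its simplicity and
auditability. Two keys may share a URI; both the hit tally and the
unique-URI tally are reported. Taxon-scope annotation unions the unique
URIs over a taxon's objects, which permits a coarser dictionary when the
goal is labelling taxa rather than paragraphs.

**Association extraction.** Only objects in the four ecology subchapters
(Associations, Trophic Strategy, General Ecology, Habitat) are read, on the
assumption that a taxon mentioned there interacts ecologically with the
page's subject; mentions elsewhere (descriptions, distribution notes) are
the dominant source of missed associations and are excluded on purpose to
protect precision. The name finder is rule-based: a binomial grammar
(capitalized latinate genus + lowercase latinate epithet, letters only,
length ≥ 2, optional internal hyphen as in *Pseudo-nitzschia*), genus
uninomials, abbreviated binomials ("C. pipiens") expanded to the nearest
preceding compatible genus in the same text, and table-exact scanning for
names the grammar cannot carry (virus names such as Tobacco mosaic virus).
Strict mode — the default — only returns candidates verified against the
names table, because for an aggregator ingesting the output precision
matters far more than recall; heuristic mode adds unverified grammar
candidates with a blacklist suppressing sentence-initial English collisions
("No names here…"). Overlaps resolve longest-match-first, verified before
unverified, so a binomial always beats its embedded genus uninomial.
Resolution is exact (case-insensitive, whitespace-normalized) with a single
synonym hop against whatever authority table is supplied; no fuzzy
matching, no multi-authority merging. Unresolved mentions are excluded from
edges by default but can be retained keyed by their canonical string.

Edges are directed (page subject → mentioned taxon) because the source
relation is asymmetric; an undirected collapse is available at export.
Multiplicity collapses to one edge with a supporting-object count. Two
filters address the documented false-positive classes: self-mentions of the
page's subject (on by default) and the higher-taxon filter (off by default,
matching how the original workflow ran) which drops an edge to a taxon that
is an ancestor — via the parent-id chain — of another taxon resolved on the
same page.

## Evaluation

Precision, recall and F1 are computed from confusion counts, F1 as the
harmonic mean of *unrounded* precision and recall; 0/0 ratios are 0 by
convention. Reports print metrics at 3 decimals and percentages at 0
decimals, both half-up (Decimal-based, so 0.9375 → 0.938); cells are left
blank for units whose tp, fp and fn are all zero. Micro totals always come
from summed counts, so the TOTAL row equals `compute_metrics(sum)` exactly.
A known wrinkle of the bundled reference tables: a few printed per-species
recalls are not consistent with their own printed TP/FN counts (e.g. an
overall recall printed as 0.930 where the counts give 494/537 ≈ 0.920);
this package always computes from counts and treats only internally
consistent printed values as reproduction targets.

The URI task has no natural negative class, so tn = 0 there. The
association task's true negatives require a candidate universe that is
nowhere canonically defined; the default here — every (subject,
resolved-mention) pair the name finder produces anywhere on each page, any
subchapter — is an interpretive choice, kept explicit and overridable by
passing a different universe to `compare_associations`.

Fleiss' kappa is implemented directly (κ = (P̄ − P̄e)/(1 − P̄e) from the
items × categories count table) so the degenerate case P̄e = 1 can raise a
typed error rather than return NaN; the test suite cross-checks it against
statsmodels and against a hand-worked 5-item oracle (κ = 11/56).

Error categories (negation, describing related taxa, word part,
generalities, homonym) are *labels carried by gold fixtures*, not automatic
classifications: the report counts which planted traps fired, by category.

## Synthetic data

The generator assembles prose from fixed sentence templates — not a
language model — so gold is exact by construction and output is
byte-identical under a fixed seed (one `random.Random` stream; no global
state). Dictionary terms are planted as verbatim stem-bearing words
(Poisson count per object, mean 2.1, matching the observed mean tags per
object in the reference corpus and leaving ~12% of objects untagged);
associations are planted as binomial mentions of pool taxa in ecology
objects (Poisson mean 2 per object, a free choice exposed in config since
no empirical distribution is available). A configurable fraction of
mentions (default 36/583 ≈ 6%, the reference share of "old" names) use a
planted synonym; 10% add an abbreviated-genus restatement. Trap sentences
plant each error category at per-object rates proportioned from the
reference error mix (57 categorized errors over 487 objects), each trap
using a key disjoint from the object's gold keys so expected false
positives are exactly countable. Default shape: 21 subject taxa with 2–30
objects each and half the objects in ecology subchapters. Generated
latinate names are rejection-sampled so they never contain a dictionary
stem, and templates avoid stem collisions; tests enforce both.

What the generator does **not** emulate: real English syntax and
vocabulary breadth, provider heterogeneity and duplicated content,
OCR/formatting noise, document length extremes (real objects span 1 to
>12,000 words), and real taxonomy beyond a one-level genus parent. Passing
tests therefore demonstrate the pipeline's internal correctness —
annotation equals a brute-force oracle, extraction inverts the generator
exactly when traps are off, planted errors are recovered where expected —
not field performance on real aggregator text.

## Numerical and design choices

- Markup cleaning uses lxml's HTML parser with a regex fallback for
  unparseable fragments; entities are decoded to a fixed point so cleaning
  is idempotent; text is NFC-normalized at load for stable substring
  matching; whitespace runs collapse to single spaces.
- Subchapter labels compare space- and case-insensitively ("Trophic
  Strategy" ≡ "TrophicStrategy"); the inclusion filter defaults to English
  and trusted-only objects.
- Dictionary keys are stored exactly as given (no automatic stemming) and
  must be pre-lowercased; the linter flags substring key pairs, keys
  shorter than 4 characters, and shared URIs. One published example entry
  spells "uterine cannibalsm"; the importer keeps keys verbatim, and the
  tolerant `'key': 'value'` importer exists for dictionaries kept in that
  literal style. A misspelled stem simply never matches correctly spelled
  text.
- Determinism throughout: objects iterate in (taxon_id, object_id) order,
  hits in dictionary order, serialized outputs sorted; identical inputs
  give identical output bytes, which the suite asserts.
- Problem sizes in tests and the acceptance script (corpora of a few
  hundred to ~1,100 objects) were chosen as the smallest sizes at which the
  binomial-tolerance checks are meaningful; everything completes in
  seconds.

## Known limitations

No live API clients: fixtures and the generator are the only data paths.
No common-name recognition by default (an optional table-exact common-name
mode exists, off to mirror the scientific-name-only behaviour of standard
name-finding services). No interaction typing (predation vs pollination),
no probabilistic name recognition, no fuzzy resolution, no automatic error
classification. Names absent from the authority pass through unresolved.
The heuristic finder's blacklist is a finite word list and will not
suppress every sentence-initial collision.
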