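"""Seeded generator of synthetic corpora with planted, fully-known gold.

Prose is assembled from fixed sentence templates — not a language model —
so every planted dictionary term, scientific-name mention and trap sentence
is recorded exactly and the generator is deterministic and auditable: the
same config and seed reproduce byte-identical corpora and gold files.

What is planted:

* dictionary stems, as verbatim stem-bearing words, recorded per object in
  the gold annotation set (Poisson-distributed count per object, default
  mean 2.1 terms);
* scientific-name mentions of pool taxa inside ecology-subchapter objects,
  recorded as gold associations; a configurable fraction use a synonym
  instead of the accepted binomial, or add an abbreviated-genus restatement;
* trap sentences for the five documented annotation error modes (negation,
  describing related taxa, word part, generalities, homonym), recorded as
  expected false positives with their category label;
* optional network traps: self mentions of the page's subject and mentions
  of a partner's genus alongside the partner (the higher-taxon error class).

Default rates emulate the published EOL evaluation of these workflows:
per-object trap rates proportioned from its 57 categorized errors over 487
objects, a 6% synonym share among mentions, and two planted associations
per ecology object.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .corpus import Corpus, ECOLOGY_SUBCHAPTERS, Taxon, TextObject
from .dictionary import Dictionary
from .errors import ConfigurationError
from .evaluation import ERROR_CATEGORIES, GoldAnnotationSet, GoldAssociationSet

__all__ = ["SynthConfig", "generate_corpus", "default_stem_dictionary", "STEM_WORDS"]

#: Stem key → a natural word containing it, used when planting terms.
STEM_WORDS = {
    "predat": "predation",
    "migrat": "migration",
    "hibernat": "hibernation",
    "pollinat": "pollination",
    "parasit": "parasitism",
    "symbio": "symbiosis",
    "herbivor": "herbivory",
    "carnivor": "carnivory",
    "scaveng": "scavenging",
    "nectar": "nectar feeding",
    "burrow": "burrowing",
    "nocturn": "nocturnal foraging",
    "spawn": "spawning",
    "venom": "venomous defense",
    "camoufl": "camouflage",
    "territor": "territoriality",
    "ovipar": "oviparity",
    "filtrat": "filtration feeding",
    "commensal": "commensalism",
    "mutualis": "mutualism",
}


def default_stem_dictionary() -> Dictionary:
    """Twenty ecological stem keys with concept URIs, one URI per key."""
    d = Dictionary(provenance="builtin:default_stem_dictionary")
    for stem, word in STEM_WORDS.items():
        concept = word.split()[0].capitalize()
        d.add(stem, f"http://dbpedia.org/resource/{concept}")
    return d


_OPENERS = (
    "This taxon is widespread throughout its range.",
    "This taxon has been the subject of many field studies.",
    "Observers describe this taxon as locally abundant.",
)
_TERM_TMPL = (
    "Field guides describe {word} in this species.",
    "Its seasonal cycle is dominated by {word}.",
    "Naturalists have long noted {word} here.",
)
_TRAP_TMPL = {
    "negation": "This species does not {word}.",
    "related_taxa": "Its close relative {name} is well known for {word}.",
    "word_part": "It is found near the kelp {word} banks.",
    "generality": "Organisms in general, e.g. at breeding or wintering grounds, may show {word}.",
    "homonym": "In older literature the word {word} had a quite different meaning.",
}
_ASSOC_TMPL = (
    "It is often found together with {name}.",
    "Records describe repeated encounters with {name}.",
    "{name} appears throughout its habitat notes.",
)
_ABBREV_TMPL = "{name} has been recorded there on many occasions."
_SELF_TMPL = "Some authors still refer to this taxon as {name}."
_HIGHER_TMPL = "Members of the genus {name} dominate these communities."
_FILLER = (
    "General notes on morphology and distribution follow.",
    "Body size and coloration vary between localities.",
    "Further study of this group is clearly needed.",
)
_OTHER_SUBCHAPTERS = ("Description", "Distribution", "Morphology", "LifeCycle")

_SYLLABLES = ("ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ra",
              "su", "te", "vo", "xa", "zo", "chi", "dra", "lum", "mor", "pel")
_EPITHET_ENDINGS = ("us", "a", "um", "is", "ii", "ensis")

#: Per-object trap probabilities proportioned from the reference error mix
#: (57 categorized errors over 487 annotated objects: 4/21/11/10/11).
DEFAULT_TRAP_RATES = {
    "negation": 0.008,
    "related_taxa": 0.043,
    "word_part": 0.023,
    "generality": 0.021,
    "homonym": 0.023,
}


@dataclass
class SynthConfig:
    """Conditions for one synthetic corpus; seed-fixed output is bit-identical."""

    n_taxa: int = 21
    objects_per_taxon: tuple[int, int] = (2, 30)
    dictionary: Dictionary | None = None       # None → default_stem_dictionary()
    name_pool: list[Taxon] | None = None       # None → generated latinate pool
    terms_per_object: float = 2.1              # Poisson mean of planted stems
    association_density: float = 2.0           # Poisson mean per ecology object
    trap_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAP_RATES))
    ecology_fraction: float = 0.5
    synonym_rate: float = 36 / 583             # share of mentions via a synonym
    abbreviation_rate: float = 0.1             # add an abbreviated restatement
    self_mention_rate: float = 0.0             # subject named in its own text
    higher_taxon_rate: float = 0.0             # partner's genus also named
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ConfigurationError("n_taxa must be >= 1")
        probs = [*self.trap_rates.values(), self.ecology_fraction,
                 self.synonym_rate, self.abbreviation_rate,
                 self.self_mention_rate, self.higher_taxon_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all rates must lie in [0, 1]")
        if (self.dictionary is not None and len(self.dictionary) == 0
                and self.name_pool is not None and not self.name_pool):
            raise ConfigurationError(
                "dictionary and name_pool cannot both be empty"
            )
        unknown = set(self.trap_rates) - set(ERROR_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown trap categories {sorted(unknown)}")


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's algorithm; exact for the small means used here."""
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _latinate_word(rng: random.Random, n_syl: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syl))


def _make_name_pool(rng: random.Random, n: int, keys: list[str]) -> list[Taxon]:
    """Generate n species taxa (each with one synonym) plus their genus taxa."""

    def fresh_word(n_syl: int, used: set[str]) -> str:
        while True:
            w = _latinate_word(rng, n_syl)
            if w in used:
                continue
            if any(k in w for k in keys):
                continue  # names must never contain dictionary stems
            used.add(w)
            return w

    def fresh_epithet(used: set[str]) -> str:
        while True:
            w = _latinate_word(rng, rng.randint(2, 3)) + rng.choice(_EPITHET_ENDINGS)
            if w not in used and not any(k in w for k in keys):
                used.add(w)
                return w

    used: set[str] = set()
    taxa: list[Taxon] = []
    for i in range(n):
        genus = fresh_word(rng.randint(2, 3), used).capitalize()
        syn_genus = fresh_word(rng.randint(2, 3), used).capitalize()
        epithet = fresh_epithet(used)
        genus_id = f"G{i:03d}"
        taxa.append(Taxon(
            taxon_id=f"T{i:04d}",
            canonical_name=f"{genus} {epithet}",
            rank="species",
            parent_id=genus_id,
            synonyms={f"{syn_genus} {epithet}"},
        ))
        taxa.append(Taxon(taxon_id=genus_id, canonical_name=genus, rank="genus"))
    return taxa


def generate_corpus(
    config: SynthConfig,
) -> tuple[Corpus, GoldAnnotationSet, GoldAssociationSet]:
    """Generate a corpus bundle plus its gold annotation and association sets."""
    config.validate()
    rng = random.Random(config.seed)

    dictionary = (config.dictionary if config.dictionary is not None
                  else default_stem_dictionary())
    keys = list(dictionary)
    if config.name_pool is not None:
        pool = list(config.name_pool)
        taxa = list(pool)
    else:
        taxa = _make_name_pool(rng, config.n_taxa, keys)
        pool = [t for t in taxa if t.rank == "species"]

    subjects = [t for t in pool][: config.n_taxa]
    corpus = Corpus(taxa={t.taxon_id: t for t in taxa})
    gold_ann = GoldAnnotationSet()
    gold_assoc = GoldAssociationSet()

    oid = 0
    for subject in subjects:
        n_obj = rng.randint(*config.objects_per_taxon)
        corpus.objects[subject.taxon_id] = []
        for _ in range(n_obj):
            oid += 1
            object_id = f"O{oid:05d}"
            is_ecology = rng.random() < config.ecology_fraction
            subchapter = (rng.choice(ECOLOGY_SUBCHAPTERS) if is_ecology
                          else rng.choice(_OTHER_SUBCHAPTERS))
            sentences = [rng.choice(_OPENERS)]
            gold_ann.uris.setdefault(object_id, set())

            # planted dictionary terms (gold positives)
            n_terms = min(_poisson(rng, config.terms_per_object), len(keys))
            gold_keys = rng.sample(keys, n_terms) if n_terms else []
            for k in gold_keys:
                word = STEM_WORDS.get(k, k)
                sentences.append(rng.choice(_TERM_TMPL).format(word=word))
                gold_ann.uris[object_id].add(dictionary[k])

            # trap sentences (expected false positives, labelled by category)
            gold_uris = {dictionary[k] for k in gold_keys}
            avail = [k for k in keys
                     if k not in gold_keys and dictionary[k] not in gold_uris]
            for cat in ERROR_CATEGORIES:
                rate = config.trap_rates.get(cat, 0.0)
                if rate <= 0 or not avail or rng.random() >= rate:
                    continue
                k = avail.pop(rng.randrange(len(avail)))
                word = STEM_WORDS.get(k, k)
                if cat == "related_taxa":
                    relatives = [t for t in pool if t.taxon_id != subject.taxon_id]
                    rel = rng.choice(relatives) if relatives else subject
                    sentences.append(_TRAP_TMPL[cat].format(
                        word=word, name=rel.canonical_name))
                    if is_ecology and rel.taxon_id != subject.taxon_id:
                        gold_assoc.pairs.add((subject.taxon_id, rel.taxon_id))
                else:
                    sentences.append(_TRAP_TMPL[cat].format(word=word))
                gold_ann.expected_fps.append((object_id, dictionary[k], cat))

            # planted associations (ecology objects only)
            if is_ecology:
                partners = [t for t in pool if t.taxon_id != subject.taxon_id]
                n_assoc = min(_poisson(rng, config.association_density),
                              len(partners))
                for partner in rng.sample(partners, n_assoc):
                    if rng.random() < config.synonym_rate and partner.synonyms:
                        name = sorted(partner.synonyms)[0]
                    else:
                        name = partner.canonical_name
                    sentences.append(rng.choice(_ASSOC_TMPL).format(name=name))
                    if " " in name and rng.random() < config.abbreviation_rate:
                        genus, epithet = name.split(" ", 1)
                        sentences.append(_ABBREV_TMPL.format(
                            name=f"{genus[0]}. {epithet}"))
                    if (config.higher_taxon_rate > 0
                            and partner.parent_id is not None
                            and rng.random() < config.higher_taxon_rate):
                        parent = corpus.taxa.get(partner.parent_id)
                        if parent is not None:
                            sentences.append(_HIGHER_TMPL.format(
                                name=parent.canonical_name))
                    gold_assoc.pairs.add((subject.taxon_id, partner.taxon_id))
                if rng.random() < config.self_mention_rate:
                    sentences.append(_SELF_TMPL.format(
                        name=subject.canonical_name))

            sentences.append(rng.choice(_FILLER))
            corpus.objects[subject.taxon_id].append(TextObject(
                object_id=object_id,
                taxon_id=subject.taxon_id,
                subchapter=subchapter,
                body=" ".join(sentences),
            ))

    corpus.validate()
    return corpus, gold_ann, gold_assoc
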