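import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from taxatext.corpus import Corpus, Taxon, TextObject
from taxatext.dictionary import Dictionary
from taxatext.resolver import NamesRecord, NamesTable


@pytest.fixture
def toy_dictionary() -> Dictionary:
    d = Dictionary()
    d.add("predat", "http://dbpedia.org/resource/Predation")
    d.add("migrat", "http://dbpedia.org/resource/Migration")
    d.add("forest", "http://dbpedia.org/resource/Forest")
    return d


@pytest.fixture
def toy_table() -> NamesTable:
    t = NamesTable()
    t.add(NamesRecord("Panthera leo", "Panthera leo", "328672", "current",
                      "species", "G-panthera"))
    t.add(NamesRecord("Panthera", "Panthera", "G-panthera", "current", "genus"))
    t.add(NamesRecord("Felis leo", "Panthera leo", "328672", "synonym"))
    t.add(NamesRecord("Carcharodon carcharias", "Carcharodon carcharias",
                      "213726", "current", "species"))
    t.add(NamesRecord("Culex pipiens", "Culex pipiens", "740671", "current"))
    t.add(NamesRecord("Tobacco mosaic virus", "Tobacco mosaic virus",
                      "8615186", "current"))
    t.validate()
    return t


@pytest.fixture
def mixed_corpus() -> Corpus:
    """Ten objects across two taxa; exactly four carry ecology subchapters."""
    taxa = {
        "T1": Taxon("T1", "Panthera leo"),
        "T2": Taxon("T2", "Carcharodon carcharias"),
    }
    labels = [
        ("O01", "T1", "Habitat"),
        ("O02", "T1", "Description"),
        ("O03", "T1", "Trophic Strategy"),
        ("O04", "T1", "Distribution"),
        ("O05", "T1", "Associations"),
        ("O06", "T2", "Morphology"),
        ("O07", "T2", "GeneralEcology"),
        ("O08", "T2", "Description"),
        ("O09", "T2", "LifeCycle"),
        ("O10", "T2", "Barcode"),
    ]
    corpus = Corpus(taxa=taxa)
    for oid, tid, sub in labels:
        corpus.objects.setdefault(tid, []).append(
            TextObject(oid, tid, sub, f"Body text of {oid}."))
    corpus.validate()
    return corpus
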