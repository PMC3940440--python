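import pytest

from taxatext.corpus import Corpus, Taxon, TextObject
from taxatext.errors import UsageError
from taxatext.network import (
    Association,
    AssociationSet,
    extract_associations,
    read_network,
    summarize,
    write_network,
)
from taxatext.resolver import NamesTable
from taxatext.synthdata import SynthConfig, generate_corpus


def _corpus(body_by_subchapter):
    taxa = {
        "TX": Taxon("TX", "Xenus alpha", synonyms={"Oldxenus alpha"}),
        "TY": Taxon("TY", "Yenus beta"),
    }
    corpus = Corpus(taxa=taxa)
    corpus.objects["TX"] = [
        TextObject(f"O{i}", "TX", sub, body)
        for i, (sub, body) in enumerate(body_by_subchapter, 1)
    ]
    return corpus


@pytest.fixture
def table():
    corpus = _corpus([])
    return NamesTable.from_taxa(corpus.taxa.values())


def test_mention_in_ecology_object_yields_edge(table):
    corpus = _corpus([("TrophicStrategy", "It feeds near Yenus beta daily.")])
    assoc = extract_associations(corpus, table)
    assert assoc.pairs() == {("TX", "TY")}
    edge = list(assoc)[0]
    assert edge.provenance[0] == "O1"


def test_self_mention_is_filtered(table):
    corpus = _corpus([("Habitat", "Xenus alpha lives here with Xenus alpha.")])
    assert extract_associations(corpus, table).pairs() == set()
    kept = extract_associations(corpus, table, self_filter=False)
    assert kept.pairs() == {("TX", "TX")}


def test_synonym_mention_of_subject_is_also_self_filtered(table):
    corpus = _corpus([("Habitat", "Some call it Oldxenus alpha.")])
    assert extract_associations(corpus, table).pairs() == set()


def test_mention_outside_ecology_subchapters_is_ignored(table):
    corpus = _corpus([("Description", "Yenus beta is similar in shape.")])
    assert extract_associations(corpus, table).pairs() == set()


def test_unresolved_mentions_dropped_by_default_retained_on_request(table):
    corpus = _corpus([("Habitat", "It shares pools with Zeta gamma often.")])
    assert extract_associations(corpus, table,
                                mode="heuristic").pairs() == set()
    kept = extract_associations(corpus, table, mode="heuristic",
                                retain_unresolved=True)
    assert kept.pairs() == {("TX", "Zeta gamma")}


def test_edge_multiplicity_collapses_with_support_count(table):
    corpus = _corpus([
        ("Habitat", "Yenus beta occurs here."),
        ("Associations", "Yenus beta is eaten."),
    ])
    assoc = extract_associations(corpus, table)
    assert len(assoc) == 1
    assert assoc.edges[("TX", "TY")].n_supporting == 2


def test_higher_taxon_filter_drops_ancestor_of_co_mentioned_species():
    taxa = {
        "TS": Taxon("TS", "Subjectus primus"),
        "TP": Taxon("TP", "Partnerus duo", parent_id="GP", rank="species"),
        "GP": Taxon("GP", "Partnerus", rank="genus"),
    }
    corpus = Corpus(taxa=taxa)
    corpus.objects["TS"] = [TextObject(
        "O1", "TS", "Associations",
        "Partnerus duo visits; members of the genus Partnerus abound.")]
    table = NamesTable.from_taxa(taxa.values())
    plain = extract_associations(corpus, table)
    assert plain.pairs() == {("TS", "TP"), ("TS", "GP")}
    filtered = extract_associations(corpus, table, higher_taxon_filter=True)
    assert filtered.pairs() == {("TS", "TP")}


def test_summarize_counts():
    a = AssociationSet()
    assert summarize(a) == summarize(AssociationSet())
    assert (summarize(a).n_nodes, summarize(a).n_edges) == (0, 0)
    a.add(Association("A", "B"))
    a.add(Association("A", "C"))
    a.add(Association("A", "B"))  # duplicate pair deduplicates
    s = summarize(a)
    assert (s.n_nodes, s.n_edges) == (3, 2)


def test_write_network_tsv_round_trip(tmp_path):
    a = AssociationSet()
    a.add(Association("A", "B", ("O1", 0, "B b")))
    a.add(Association("A", "C", ("O2", 5, "C c")))
    p = tmp_path / "network.tsv"
    write_network(a, p, "tsv")
    assert len(p.read_text().splitlines()) == 3
    assert read_network(p).pairs() == a.pairs()


def test_write_network_empty_tsv_is_header_only(tmp_path):
    p = tmp_path / "network.tsv"
    write_network(AssociationSet(), p, "tsv")
    assert p.read_text().splitlines() == [
        "subject_taxon_id\tobject_taxon_id\tn_supporting_objects"]


def test_write_network_sif_and_graphml(tmp_path):
    a = AssociationSet()
    a.add(Association("A", "B"))
    sif = tmp_path / "network.sif"
    write_network(a, sif, "sif")
    assert sif.read_text() == "A\tassoc\tB\n"
    gml = tmp_path / "network.graphml"
    write_network(a, gml, "graphml")
    import networkx as nx
    g = nx.read_graphml(gml)
    assert set(g.edges) == {("A", "B")}


def test_unsupported_format_is_usage_error(tmp_path):
    with pytest.raises(UsageError):
        write_network(AssociationSet(), tmp_path / "x", "xlsx")


def test_extraction_deterministic_and_perfect_on_trap_free_synthetic(tmp_path):
    cfg = SynthConfig(seed=21, n_taxa=12, objects_per_taxon=(3, 8),
                      trap_rates={}, synonym_rate=0.0)
    corpus, _, gold = generate_corpus(cfg)
    table = NamesTable.from_taxa(corpus.taxa.values())
    a1 = extract_associations(corpus, table)
    a2 = extract_associations(corpus, table)
    p1, p2 = tmp_path / "n1.tsv", tmp_path / "n2.tsv"
    write_network(a1, p1)
    write_network(a2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    # perfect extraction against planted gold
    assert a1.pairs() == gold.pairs
    # provenance stays inside the ecology subchapters, never self edges
    eco_ids = {o.object_id for o in corpus.all_objects() if o.is_ecology}
    for edge in a1:
        assert edge.subject_taxon_id != edge.object_taxon_id
        assert edge.provenance[0] in eco_ids
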