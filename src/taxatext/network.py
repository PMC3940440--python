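"""Build the species association network from ecology-subchapter text.

The reading is deliberately coarse: a taxon mentioned in the ecology prose of
another taxon's page is taken to be associated with the page's subject.
Edges are directed (page subject → mentioned taxon), deduplicated per
(subject, object) pair with a supporting-object count, and exportable as
TSV, SIF or GraphML for downstream visualization.

Two optional filters target the documented false-positive classes:
``self_filter`` (default on) drops mentions resolving to the page's own
subject; ``higher_taxon_filter`` (default off) drops an edge to a taxon that
is an ancestor of another taxon resolved on the same page — the dominant
false-positive class when a species and its family are both named.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx

from .corpus import Corpus, ECOLOGY_SUBCHAPTERS, TextObject, filter_objects
from .errors import UsageError
from .name_finder import find_names
from .resolver import NamesTable, resolve_name

__all__ = [
    "Association",
    "AssociationSet",
    "NetworkSummary",
    "extract_associations",
    "candidate_universe",
    "summarize",
    "write_network",
    "read_network",
]


@dataclass(frozen=True)
class Association:
    """A directed subject-taxon → mentioned-taxon edge with provenance."""

    subject_taxon_id: str
    object_taxon_id: str
    provenance: tuple[str, int, str] | None = None  # (object_id, offset, verbatim)


@dataclass
class _EdgeData:
    provenance: tuple[str, int, str] | None
    supporting_objects: set[str] = field(default_factory=set)

    @property
    def n_supporting(self) -> int:
        return max(1, len(self.supporting_objects))


@dataclass
class AssociationSet:
    """Deduplicated directed edges with supporting-object counts."""

    edges: dict[tuple[str, str], _EdgeData] = field(default_factory=dict)

    def add(self, assoc: Association) -> None:
        key = (assoc.subject_taxon_id, assoc.object_taxon_id)
        data = self.edges.get(key)
        if data is None:
            data = self.edges[key] = _EdgeData(assoc.provenance)
        if assoc.provenance is not None:
            data.supporting_objects.add(assoc.provenance[0])

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def nodes(self) -> set[str]:
        return {n for pair in self.edges for n in pair}

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        for s, o in sorted(self.edges):
            yield Association(s, o, self.edges[(s, o)].provenance)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int


def summarize(a: AssociationSet) -> NetworkSummary:
    return NetworkSummary(n_nodes=len(a.nodes()), n_edges=len(a))


def extract_associations(
    corpus: Corpus,
    table: NamesTable,
    subchapters: Iterable[str] = ECOLOGY_SUBCHAPTERS,
    mode: Literal["strict", "heuristic"] = "strict",
    self_filter: bool = True,
    higher_taxon_filter: bool = False,
    retain_unresolved: bool = False,
    language: str | None = "en",
    trusted_only: bool = True,
    include_common_names: bool = False,
) -> AssociationSet:
    """Run the full pipeline: filter → find names → resolve → filter → dedupe."""
    result = AssociationSet()
    for obj in filter_objects(corpus, subchapters, language, trusted_only):
        subject_id = obj.taxon_id
        mentions = find_names(obj.body, table, mode,
                              include_common_names=include_common_names)
        resolved = [(m, resolve_name(m.canonical, table)) for m in mentions]

        page_taxa = {r.taxon_id for _, r in resolved if r.matched}
        dropped_ancestors: set[str] = set()
        if higher_taxon_filter:
            for tid in page_taxa:
                others = page_taxa - {tid}
                for other in others:
                    if tid in table.ancestors(other):
                        dropped_ancestors.add(tid)
                        break

        for mention, res in resolved:
            if res.matched:
                target = res.taxon_id
                if self_filter and target == subject_id:
                    continue
                if higher_taxon_filter and target in dropped_ancestors:
                    continue
            else:
                if not retain_unresolved:
                    continue
                target = mention.canonical
                subj = corpus.taxa.get(subject_id)
                if self_filter and subj is not None and (
                    target == subj.canonical_name or target in subj.synonyms
                ):
                    continue
            result.add(Association(
                subject_id, target,
                provenance=(obj.object_id, mention.offset, mention.verbatim),
            ))
    return result


def candidate_universe(
    corpus: Corpus,
    table: NamesTable,
    mode: Literal["strict", "heuristic"] = "strict",
    language: str | None = "en",
    trusted_only: bool = True,
) -> set[tuple[str, str]]:
    """Candidate (subject, mentioned-taxon) pairs for true-negative counting.

    The universe is every pair the name finder produces anywhere on each
    page — any subchapter, no self pairs.  The association task has no
    natural negative class, so this interpretive choice is kept explicit
    and configurable by passing a different universe to the evaluator.
    """
    universe: set[tuple[str, str]] = set()
    subchapters = {obj.subchapter for objs in corpus.objects.values() for obj in objs}
    if not subchapters:
        return universe
    for obj in filter_objects(corpus, subchapters, language, trusted_only):
        for m in find_names(obj.body, table, mode):
            res = resolve_name(m.canonical, table)
            if res.matched and res.taxon_id != obj.taxon_id:
                universe.add((obj.taxon_id, res.taxon_id))
    return universe


def write_network(
    a: AssociationSet,
    path: str | Path,
    format: Literal["tsv", "sif", "graphml"] = "tsv",
    directed: bool = True,
) -> None:
    """Export the edge set; the TSV form round-trips via :func:`read_network`."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["subject_taxon_id", "object_taxon_id", "n_supporting_objects"])
            for s, o in sorted(a.edges):
                w.writerow([s, o, a.edges[(s, o)].n_supporting])
    elif format == "sif":
        lines = [f"{s}\tassoc\t{o}" for s, o in sorted(a.edges)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "graphml":
        g = nx.DiGraph() if directed else nx.Graph()
        for s, o in sorted(a.edges):
            g.add_edge(s, o, n_supporting_objects=a.edges[(s, o)].n_supporting)
        nx.write_graphml(g, path)
    else:
        raise UsageError(f"unsupported network format {format!r}")


def read_network(path: str | Path) -> AssociationSet:
    """Read a TSV network back into a (provenance-free) AssociationSet."""
    result = AssociationSet()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["subject_taxon_id"], row["object_taxon_id"])
            data = result.edges.get(key)
            if data is None:
                result.edges[key] = _EdgeData(None)
    return result
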