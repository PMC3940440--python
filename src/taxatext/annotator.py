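"""Tag text objects with concept URIs by lowercase substring search of stems.

The procedure is deliberately simple: the body is lowercased once, then each
dictionary key is searched for as a contiguous substring.  The first
occurrence of a key yields one hit and the scan moves on to the next key.
Matching crosses word boundaries by design — that is what makes a stem like
``predat`` cover predator/predation/predatory — and the resulting word-part
false positives (e.g. ``forest`` firing inside "kelp forest") are accepted
behaviour here and measured by the evaluation module, not prevented.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .corpus import Corpus, TextObject
from .dictionary import Dictionary
from .errors import UsageError

__all__ = [
    "AnnotationHit",
    "AnnotationResult",
    "annotate_object",
    "annotate_corpus",
    "write_annotations",
    "read_annotations",
]


@dataclass(frozen=True)
class AnnotationHit:
    """First occurrence of one dictionary key in one body."""

    key: str
    uri: str
    offset: int  # 0-based index of the first match in the lowercased body
    source_object_id: str | None = None  # set for taxon-scope results


@dataclass
class AnnotationResult:
    """All hits for one unit (a text object, or a taxon under taxon scope).

    ``hits`` holds at most one entry per dictionary key, in dictionary
    order; ``unique_uris`` collapses keys sharing a URI, mirroring the
    distinction between total and unique tag tallies.
    """

    object_id: str
    hits: list[AnnotationHit] = field(default_factory=list)

    @property
    def unique_uris(self) -> set[str]:
        return {h.uri for h in self.hits}


def annotate_object(obj: TextObject, d: Dictionary) -> AnnotationResult:
    """Annotate one text object. An empty-hit result is valid output."""
    body = obj.body.lower()
    hits = []
    for key, uri in d.items():
        idx = body.find(key)
        if idx >= 0:
            hits.append(AnnotationHit(key, uri, idx, obj.object_id))
    return AnnotationResult(obj.object_id, hits)


def annotate_corpus(
    corpus: Corpus,
    d: Dictionary,
    scope: Literal["object", "taxon"] = "object",
) -> dict[str, AnnotationResult]:
    """Annotate every text object, or aggregate per taxon.

    Object scope returns one result per text object keyed by object_id.
    Taxon scope returns one result per taxon whose hits are the union over
    that taxon's objects; for each key the earliest hit (first object in
    object_id order, then lowest offset) is kept as provenance.
    """
    if scope not in ("object", "taxon"):
        raise UsageError(f"unknown annotation scope {scope!r}")
    if scope == "object":
        return {o.object_id: annotate_object(o, d) for o in corpus.all_objects()}

    results: dict[str, AnnotationResult] = {}
    for tid in sorted(corpus.taxa):
        per_key: dict[str, AnnotationHit] = {}
        for obj in sorted(corpus.objects.get(tid, []), key=lambda o: o.object_id):
            for hit in annotate_object(obj, d).hits:
                per_key.setdefault(hit.key, hit)
        hits = [per_key[k] for k in d if k in per_key]
        results[tid] = AnnotationResult(tid, hits)
    return results


def write_annotations(
    results: Mapping[str, AnnotationResult], path: str | Path
) -> None:
    """Write hits as TSV (object_id, key, uri, offset), sorted by object_id."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["object_id", "key", "uri", "offset"])
        for oid in sorted(results):
            for h in results[oid].hits:
                w.writerow([oid, h.key, h.uri, h.offset])


def read_annotations(path: str | Path) -> dict[str, AnnotationResult]:
    results: dict[str, AnnotationResult] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            res = results.setdefault(row["object_id"], AnnotationResult(row["object_id"]))
            res.hits.append(
                AnnotationHit(row["key"], row["uri"], int(row["offset"]), row["object_id"])
            )
    return results
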