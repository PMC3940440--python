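"""Data model and I/O for taxon pages and their narrative text objects.

A *corpus bundle* is a JSON document holding taxa and their attached text
objects (see ``docs/formats.md``).  Bodies are cleaned of markup at load time
and normalized to NFC so that downstream substring matching is stable.

The ecology subchapter set used throughout the package is the one an
aggregator files interaction-bearing prose under: Associations, Trophic
Strategy, General Ecology and Habitat.  Labels are compared after stripping
spaces and case, so "Trophic Strategy" and "TrophicStrategy" are equivalent.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from html import unescape
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree
from lxml import html as lxml_html

from .errors import IntegrityError, ParseError

__all__ = [
    "ECOLOGY_SUBCHAPTERS",
    "TextObject",
    "Taxon",
    "Corpus",
    "clean_markup",
    "filter_objects",
    "load_corpus",
    "save_corpus",
    "normalize_subchapter",
]

#: Subchapter labels whose prose is read as describing ecological interactions.
ECOLOGY_SUBCHAPTERS: tuple[str, ...] = (
    "Associations",
    "TrophicStrategy",
    "GeneralEcology",
    "Habitat",
)

_TAG_RE = re.compile(r"<[^>]+>")
_WS_RE = re.compile(r"\s+")


def normalize_subchapter(label: str) -> str:
    """Canonical form of a subchapter label: spaces stripped, lowercased."""
    return label.replace(" ", "").lower()


_ECOLOGY_NORM = frozenset(normalize_subchapter(s) for s in ECOLOGY_SUBCHAPTERS)


def _unescape_fixpoint(s: str) -> str:
    # decode to a fixed point so cleaning already-cleaned text is a no-op
    while "&" in s:
        decoded = unescape(s)
        if decoded == s:
            break
        s = decoded
    return s


def clean_markup(raw: str) -> str:
    """Strip markup from ``raw`` and return plain text.

    Tags are removed, character entities decoded, whitespace runs collapsed
    to single spaces, and the result NFC-normalized and stripped.  The
    function is tolerant of malformed markup (best-effort strip) and
    idempotent.
    """
    text = raw
    if _TAG_RE.search(raw):
        try:
            tree = lxml_html.fromstring(raw)
            text = " ".join(tree.itertext())
        except (etree.ParserError, etree.XMLSyntaxError, ValueError):
            text = _TAG_RE.sub(" ", raw)
    text = _unescape_fixpoint(text)
    text = unicodedata.normalize("NFC", text)
    return _WS_RE.sub(" ", text).strip()


@dataclass(frozen=True)
class TextObject:
    """One narrative data object attached to a taxon page."""

    object_id: str
    taxon_id: str
    subchapter: str
    body: str
    language: str = "en"
    trusted: bool = True
    source: str = ""

    @property
    def is_ecology(self) -> bool:
        return normalize_subchapter(self.subchapter) in _ECOLOGY_NORM

    @property
    def word_count(self) -> int:
        return len(self.body.split())


@dataclass
class Taxon:
    """A taxon page: identifier, accepted scientific name and name variants."""

    taxon_id: str
    canonical_name: str
    rank: str | None = None
    parent_id: str | None = None
    synonyms: set[str] = field(default_factory=set)
    common_names: set[str] = field(default_factory=set)


@dataclass
class Corpus:
    """Taxa plus their text objects, with global object-id uniqueness."""

    taxa: dict[str, Taxon] = field(default_factory=dict)
    objects: dict[str, list[TextObject]] = field(default_factory=dict)

    def all_objects(self) -> Iterator[TextObject]:
        """All text objects in deterministic (taxon_id, object_id) order."""
        for tid in sorted(self.objects):
            yield from sorted(self.objects[tid], key=lambda o: o.object_id)

    def n_objects(self) -> int:
        return sum(len(v) for v in self.objects.values())

    def validate(self) -> None:
        seen: set[str] = set()
        for tid, taxon in self.taxa.items():
            if not taxon.canonical_name:
                raise IntegrityError(f"taxon {tid!r} has an empty canonical_name")
        for tid, objs in self.objects.items():
            if tid not in self.taxa:
                raise IntegrityError(
                    f"text objects reference unknown taxon_id {tid!r}"
                )
            for obj in objs:
                if obj.object_id in seen:
                    raise IntegrityError(f"duplicate object_id {obj.object_id!r}")
                seen.add(obj.object_id)
                if obj.taxon_id != tid:
                    raise IntegrityError(
                        f"object {obj.object_id!r} filed under taxon {tid!r} "
                        f"but carries taxon_id {obj.taxon_id!r}"
                    )
                if obj.word_count < 1:
                    raise IntegrityError(
                        f"object {obj.object_id!r} has an empty body"
                    )
                if _TAG_RE.search(obj.body):
                    raise IntegrityError(
                        f"object {obj.object_id!r} body contains markup tags"
                    )


def filter_objects(
    corpus: Corpus,
    subchapters: Iterable[str] = ECOLOGY_SUBCHAPTERS,
    language: str | None = "en",
    trusted_only: bool = True,
) -> list[TextObject]:
    """Select text objects by subchapter, language and trust flag.

    Subchapter labels are compared space- and case-insensitively.  The result
    is deterministically ordered by (taxon_id, object_id).
    """
    wanted = {normalize_subchapter(s) for s in subchapters}
    if not wanted:
        raise ValueError("subchapters must be non-empty")
    out = []
    for obj in corpus.all_objects():
        if normalize_subchapter(obj.subchapter) not in wanted:
            continue
        if language is not None and obj.language != language:
            continue
        if trusted_only and not obj.trusted:
            continue
        out.append(obj)
    return out


def _taxon_to_json(t: Taxon) -> dict:
    return {
        "taxon_id": t.taxon_id,
        "canonical_name": t.canonical_name,
        "rank": t.rank,
        "parent_id": t.parent_id,
        "synonyms": sorted(t.synonyms),
        "common_names": sorted(t.common_names),
    }


def _object_to_json(o: TextObject) -> dict:
    return {
        "object_id": o.object_id,
        "taxon_id": o.taxon_id,
        "subchapter": o.subchapter,
        "body": o.body,
        "language": o.language,
        "trusted": o.trusted,
        "source": o.source,
    }


def load_corpus(path: str | Path) -> Corpus:
    """Load a corpus bundle (JSON), cleaning bodies and validating invariants."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "taxa" not in doc or "objects" not in doc:
        raise ParseError(f"{path}: bundle must be an object with 'taxa' and 'objects'")

    corpus = Corpus()
    for rec in doc["taxa"]:
        try:
            taxon = Taxon(
                taxon_id=str(rec["taxon_id"]),
                canonical_name=unicodedata.normalize("NFC", rec["canonical_name"]),
                rank=rec.get("rank") or None,
                parent_id=rec.get("parent_id") or None,
                synonyms=set(rec.get("synonyms", ())),
                common_names=set(rec.get("common_names", ())),
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: malformed taxon record {rec!r}") from exc
        if taxon.taxon_id in corpus.taxa:
            raise IntegrityError(f"{path}: duplicate taxon_id {taxon.taxon_id!r}")
        corpus.taxa[taxon.taxon_id] = taxon

    for rec in doc["objects"]:
        try:
            obj = TextObject(
                object_id=str(rec["object_id"]),
                taxon_id=str(rec["taxon_id"]),
                subchapter=rec["subchapter"],
                body=clean_markup(rec["body"]),
                language=rec.get("language", "en"),
                trusted=bool(rec.get("trusted", True)),
                source=rec.get("source", ""),
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: malformed object record {rec!r}") from exc
        corpus.objects.setdefault(obj.taxon_id, []).append(obj)

    corpus.validate()
    return corpus


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus bundle; ``load_corpus`` round-trips it exactly."""
    doc = {
        "taxa": [_taxon_to_json(corpus.taxa[t]) for t in sorted(corpus.taxa)],
        "objects": [_object_to_json(o) for o in corpus.all_objects()],
    }
    Path(path).write_text(
        json.dumps(doc, ensure_ascii=False, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
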