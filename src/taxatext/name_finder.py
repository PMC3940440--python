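"""Locate scientific-name mentions in plain text.

A local, rule-based name finder: a binomial grammar (capitalized latinate
genus + lowercase latinate epithet), genus uninomials, abbreviated binomials
("C. pipiens", expanded to the nearest preceding compatible genus in the
same text) and table-exact matching for names the grammar cannot carry
(virus names and other non-latinate forms).

Two modes:

* ``strict`` (default) returns only candidates verified against a names
  table — deterministic and high-precision, which is what an aggregator
  ingesting the output wants.
* ``heuristic`` additionally returns unverified binomial-grammar candidates,
  with a blacklist suppressing sentence-initial English collisions
  ("No names here ..." is not a species).

Overlapping candidates are resolved longest-match-first, with verified
candidates taking precedence over unverified ones; reported mentions never
overlap and offsets strictly increase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .errors import ConfigurationError, UsageError
from .resolver import NamesTable

__all__ = ["NameMention", "find_names", "write_mentions", "DEFAULT_BLACKLIST"]

# Latinate token: letters only, length >= 2, optional internal hyphen
# (covers hyphenated genera such as "Pseudo-nitzschia").
_GENUS = r"[A-Z][a-z]+(?:-[a-z]+)?"
_EPITHET = r"[a-z]{2,}(?:-[a-z]+)?"

BINOMIAL_RE = re.compile(rf"\b({_GENUS})[ \t]({_EPITHET})\b")
UNINOMIAL_RE = re.compile(rf"\b{_GENUS}\b")
ABBREV_RE = re.compile(rf"\b([A-Z])\.[ \t]?({_EPITHET})\b")

#: Capitalized English words that commonly start sentences and would
#: otherwise parse as a genus in heuristic mode.
DEFAULT_BLACKLIST = frozenset({
    "The", "This", "That", "These", "Those", "There", "Then", "They",
    "Their", "It", "Its", "He", "She", "We", "You", "One", "Two", "Three",
    "No", "Not", "Nor", "None", "All", "Any", "Some", "Many", "Most", "Much",
    "More", "Less", "Few", "Both", "Each", "Every", "Other", "Another",
    "Such", "Same", "Several", "Various", "Certain", "Only", "Even",
    "In", "On", "At", "Of", "For", "From", "With", "Within", "Without",
    "During", "After", "Before", "When", "Where", "While", "Although",
    "However", "Because", "Since", "Unless", "Until", "About", "Among",
    "Between", "Under", "Over", "Like", "Unlike", "New", "Old", "Large",
    "Small", "Adult", "Young", "Female", "Male", "Being", "Having",
})


@dataclass(frozen=True)
class NameMention:
    """A scientific-name string found in text."""

    verbatim: str
    offset: int
    canonical: str  # normalized: expanded genus, single spaces
    form: Literal["binomial", "uninomial", "abbreviated-binomial", "table-exact"]


@dataclass(frozen=True)
class _Cand:
    start: int
    end: int
    verbatim: str
    canonical: str
    form: str
    verified: bool


def _grammar_covers(name: str) -> bool:
    return bool(BINOMIAL_RE.fullmatch(name) or UNINOMIAL_RE.fullmatch(name))


def _resolve_overlaps(cands: list[_Cand]) -> list[_Cand]:
    """Greedy selection: verified first, then longest, then leftmost."""
    accepted: list[_Cand] = []
    for c in sorted(cands, key=lambda c: (not c.verified, c.start - c.end, c.start)):
        if all(c.end <= a.start or c.start >= a.end for a in accepted):
            accepted.append(c)
    return sorted(accepted, key=lambda c: c.start)


def find_names(
    text: str,
    table: NamesTable | None = None,
    mode: Literal["strict", "heuristic"] = "strict",
    include_common_names: bool = False,
    blacklist: frozenset[str] = DEFAULT_BLACKLIST,
) -> list[NameMention]:
    """Find scientific-name mentions in cleaned plain text.

    In strict mode a non-empty names table is required and every returned
    canonical is present in it (as accepted name, synonym, or listed name).
    """
    if mode not in ("strict", "heuristic"):
        raise UsageError(f"unknown finder mode {mode!r}")
    if mode == "strict" and (table is None or len(table) == 0):
        raise ConfigurationError("strict mode requires a non-empty names table")

    cands: list[_Cand] = []

    for m in BINOMIAL_RE.finditer(text):
        canonical = f"{m.group(1)} {m.group(2)}"
        verified = table is not None and canonical in table
        if verified or (mode == "heuristic" and m.group(1) not in blacklist):
            cands.append(_Cand(m.start(), m.end(), m.group(0), canonical,
                               "binomial", verified))

    for m in UNINOMIAL_RE.finditer(text):
        word = m.group(0)
        if table is not None and word in table:
            cands.append(_Cand(m.start(), m.end(), word, word, "uninomial", True))

    # Table-exact scan for names the grammar cannot represent
    # (e.g. "Tobacco mosaic virus"); optionally common names.
    if table is not None:
        for nm in sorted(set(table.all_names(include_common=include_common_names))):
            if _grammar_covers(nm):
                continue
            start = 0
            while (i := text.find(nm, start)) != -1:
                cands.append(_Cand(i, i + len(nm), nm, nm, "table-exact", True))
                start = i + 1

    accepted = _resolve_overlaps(cands)

    # Abbreviated binomials: expand the initial to the nearest preceding
    # compatible genus mentioned in the same text.
    abbrevs: list[_Cand] = []
    for m in ABBREV_RE.finditer(text):
        if any(m.start() < a.end and m.end() > a.start for a in accepted):
            continue
        initial, epithet = m.group(1), m.group(2)
        genus = None
        for a in reversed([a for a in accepted if a.start < m.start()]):
            g = a.canonical.split()[0]
            if g.startswith(initial):
                genus = g
                break
        if genus is None:
            continue
        canonical = f"{genus} {epithet}"
        verified = table is not None and canonical in table
        if mode == "strict" and not verified:
            continue
        abbrevs.append(_Cand(m.start(), m.end(), m.group(0), canonical,
                             "abbreviated-binomial", verified))

    final = _resolve_overlaps(accepted + abbrevs)
    return [NameMention(c.verbatim, c.start, c.canonical, c.form) for c in final]


def write_mentions(mentions_by_object: dict[str, list[NameMention]], path) -> None:
    """Write mentions.tsv (object_id, offset, verbatim, canonical, form)."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["object_id", "offset", "verbatim", "canonical", "form"])
        for oid in sorted(mentions_by_object):
            for m in mentions_by_object[oid]:
                w.writerow([oid, m.offset, m.verbatim, m.canonical, m.form])
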