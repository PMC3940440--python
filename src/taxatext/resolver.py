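"""Reconcile scientific names to accepted names and taxon identifiers.

A :class:`NamesTable` is a local authority: each row maps a name string
(current name or synonym) to its accepted name and taxon id.  Resolution is
exact — case-insensitive and whitespace-normalized — with a single synonym
hop; nothing fuzzy, so every reconciliation is auditable.  Names absent from
the table pass through unresolved and are excluded from resolved networks
but kept in mention logs.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .corpus import Taxon
from .errors import IntegrityError

__all__ = ["NamesRecord", "NamesTable", "ResolvedName", "load_names_table",
           "save_names_table", "resolve_name"]

log = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")


def _norm(name: str) -> str:
    return _WS_RE.sub(" ", name.strip()).lower()


@dataclass(frozen=True)
class NamesRecord:
    name: str
    accepted_name: str
    taxon_id: str
    status: str  # "current" | "synonym"
    rank: str | None = None
    parent_id: str | None = None


@dataclass(frozen=True)
class ResolvedName:
    """Outcome of looking one canonical mention string up in the authority."""

    input: str
    matched: bool
    accepted_name: str = ""
    taxon_id: str = ""
    was_synonym: bool = False


@dataclass
class NamesTable:
    """Authority table: normalized name → record, plus optional common names."""

    records: dict[str, NamesRecord] = field(default_factory=dict)
    common_names: dict[str, str] = field(default_factory=dict)  # norm name → taxon_id

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self.records

    def get(self, name: str) -> NamesRecord | None:
        return self.records.get(_norm(name))

    def add(self, rec: NamesRecord) -> None:
        key = _norm(rec.name)
        if key in self.records:
            raise IntegrityError(f"duplicate name row {rec.name!r}")
        if not rec.taxon_id:
            raise IntegrityError(f"name {rec.name!r} has an empty taxon_id")
        self.records[key] = rec

    def all_names(self, include_common: bool = False) -> Iterator[str]:
        """Verbatim name strings known to the table (for table-exact finding)."""
        for rec in self.records.values():
            yield rec.name
        if include_common:
            yield from self.common_names

    def by_taxon_id(self, taxon_id: str) -> NamesRecord | None:
        for rec in self.records.values():
            if rec.status == "current" and rec.taxon_id == taxon_id:
                return rec
        return None

    def ancestors(self, taxon_id: str) -> set[str]:
        """Taxon ids on the parent chain above ``taxon_id`` (cycle-safe)."""
        by_id = {r.taxon_id: r for r in self.records.values() if r.status == "current"}
        out: set[str] = set()
        cur = by_id.get(taxon_id)
        while cur is not None and cur.parent_id and cur.parent_id not in out:
            out.add(cur.parent_id)
            cur = by_id.get(cur.parent_id)
        return out

    def validate(self) -> None:
        current = {_norm(r.accepted_name) for r in self.records.values()
                   if r.status == "current"}
        current |= {_norm(r.name) for r in self.records.values()
                    if r.status == "current"}
        for rec in self.records.values():
            if rec.status == "synonym" and _norm(rec.accepted_name) not in current:
                raise IntegrityError(
                    f"synonym {rec.name!r} points to accepted name "
                    f"{rec.accepted_name!r} which has no current row"
                )

    @classmethod
    def from_taxa(cls, taxa: Iterable[Taxon]) -> "NamesTable":
        """Build an authority table from corpus taxa (accepted + synonyms)."""
        table = cls()
        taxa = list(taxa)
        for t in taxa:
            table.add(NamesRecord(t.canonical_name, t.canonical_name, t.taxon_id,
                                  "current", t.rank, t.parent_id))
        for t in taxa:
            for syn in sorted(t.synonyms):
                table.add(NamesRecord(syn, t.canonical_name, t.taxon_id, "synonym",
                                      t.rank, t.parent_id))
            for cn in sorted(t.common_names):
                table.common_names[_norm(cn)] = t.taxon_id
        table.validate()
        return table


def load_names_table(path: str | Path) -> NamesTable:
    """Load names.tsv (columns name, accepted_name, taxon_id, status[, rank, parent_id])."""
    path = Path(path)
    table = NamesTable()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            log.warning("names table %s is empty", path)
            return table
        for row in reader:
            table.add(NamesRecord(
                name=row["name"],
                accepted_name=row["accepted_name"] or row["name"],
                taxon_id=row["taxon_id"],
                status=row["status"] or "current",
                rank=(row.get("rank") or None),
                parent_id=(row.get("parent_id") or None),
            ))
    table.validate()
    return table


def save_names_table(table: NamesTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "accepted_name", "taxon_id", "status", "rank", "parent_id"])
        for key in sorted(table.records):
            r = table.records[key]
            w.writerow([r.name, r.accepted_name, r.taxon_id, r.status,
                        r.rank or "", r.parent_id or ""])


def resolve_name(name: str, table: NamesTable) -> ResolvedName:
    """Exact (case-insensitive) lookup with a single synonym hop.

    A current name resolves to itself; a synonym resolves to its accepted
    record with ``was_synonym`` set; an absent name returns matched=False.
    """
    if not name.strip():
        raise ValueError("name must be non-empty")
    rec = table.get(name)
    if rec is None:
        return ResolvedName(name, matched=False)
    return ResolvedName(
        input=name,
        matched=True,
        accepted_name=rec.accepted_name,
        taxon_id=rec.taxon_id,
        was_synonym=(rec.status == "synonym"),
    )
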