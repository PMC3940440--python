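"""The annotation dictionary: ordered lowercase stem keys mapped to concept URIs.

Keys are deliberately truncated stems (e.g. ``predat``) matched as substrings
so a single entry covers every inflection (predator, predation, predatory).
No stemming is applied here; choosing stems is the dictionary author's job.

On disk the dictionary is a two-column TSV (key, uri); ``#`` comment lines are
ignored.  A tolerant importer for Python-literal style lines
(``'key': 'http://...'``) is provided for dictionaries kept in that form.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator
from urllib.parse import urlsplit

from .errors import IntegrityError

__all__ = [
    "Dictionary",
    "Issue",
    "load_dictionary",
    "save_dictionary",
    "load_dictionary_pyliteral",
    "validate_dictionary",
]

log = logging.getLogger(__name__)

#: Keys shorter than this are flagged as collision-prone.
SHORT_KEY_LENGTH = 4


@dataclass
class Dictionary:
    """Ordered mapping of lowercase stem keys to absolute concept URIs."""

    entries: dict[str, str] = field(default_factory=dict)
    provenance: str | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> str:
        return self.entries[key]

    def items(self):
        return self.entries.items()

    def add(self, key: str, uri: str) -> None:
        _check_entry(key, uri)
        if key in self.entries:
            raise IntegrityError(f"duplicate dictionary key {key!r}")
        self.entries[key] = uri


def _check_entry(key: str, uri: str) -> None:
    if not key:
        raise IntegrityError("empty dictionary key")
    if key != key.lower():
        raise IntegrityError(
            f"dictionary key {key!r} contains uppercase characters; "
            "keys must be pre-lowercased"
        )
    if not urlsplit(uri).scheme:
        raise IntegrityError(f"malformed URI {uri!r} for key {key!r} (no scheme)")


def load_dictionary(path: str | Path) -> Dictionary:
    """Load a TSV dictionary, preserving file order and enforcing invariants."""
    path = Path(path)
    d = Dictionary(provenance=str(path))
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise IntegrityError(f"{path}:{lineno}: expected 2 tab-separated columns")
        key, uri = parts[0].strip(), parts[1].strip()
        try:
            d.add(key, uri)
        except IntegrityError as exc:
            raise IntegrityError(f"{path}:{lineno}: {exc}") from exc
    if not d.entries:
        log.warning("dictionary %s is empty", path)
    return d


_PYLITERAL_RE = re.compile(r"""['"](?P<key>[^'"]+)['"]\s*:\s*['"](?P<uri>[^'"]+)['"]""")


def load_dictionary_pyliteral(path: str | Path) -> Dictionary:
    """Tolerant importer for ``'key': 'uri'`` style dictionary listings."""
    path = Path(path)
    d = Dictionary(provenance=str(path))
    for m in _PYLITERAL_RE.finditer(path.read_text(encoding="utf-8")):
        d.add(m.group("key").lower(), m.group("uri"))
    return d


def save_dictionary(d: Dictionary, path: str | Path) -> None:
    lines = [f"{k}\t{u}" for k, u in d.entries.items()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


@dataclass(frozen=True)
class Issue:
    """One dictionary-quality finding from :func:`validate_dictionary`."""

    code: str  # substring-key | short-key | shared-uri
    severity: str  # warning | info
    keys: tuple[str, ...]
    message: str


def validate_dictionary(d: Dictionary) -> list[Issue]:
    """Lint a dictionary for constructions known to distort metrics.

    Returns substring-key warnings (both keys fire on the longer term's
    text), short-key warnings (< 4 characters, high collision risk) and
    shared-URI notes (several keys mapping to one URI — legitimate, but the
    unique-URI tally will differ from the hit tally).
    """
    issues: list[Issue] = []
    keys = list(d.entries)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
            if shorter in longer:
                issues.append(Issue(
                    "substring-key", "warning", (shorter, longer),
                    f"key {shorter!r} is a substring of key {longer!r}; "
                    f"both will fire on text containing {longer!r}",
                ))
    for k in keys:
        if len(k) < SHORT_KEY_LENGTH:
            issues.append(Issue(
                "short-key", "warning", (k,),
                f"key {k!r} is shorter than {SHORT_KEY_LENGTH} characters "
                "(high collision risk)",
            ))
    by_uri: dict[str, list[str]] = {}
    for k, u in d.entries.items():
        by_uri.setdefault(u, []).append(k)
    for uri, ks in by_uri.items():
        if len(ks) > 1:
            issues.append(Issue(
                "shared-uri", "info", tuple(ks),
                f"keys {ks} all map to {uri}",
            ))
    return issues
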