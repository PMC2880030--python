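"""Dictionary-based ontology term tagging with the longest-match rule.

Terms and their EXACT synonyms from OBO ontologies are compiled into a
surface-form dictionary; article text is scanned left to right over token
boundaries and, wherever several dictionary entries match, only the
longest one is emitted (so ``zinc finger`` beats ``zinc`` and the scan
resumes after it).  Matching is case-insensitive and token-aligned — a
term never fires inside a longer word, so ``cat`` cannot match within
``catalysis``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import obonet

from .corpus import Article, iter_text_units

__all__ = ["TermDictionary", "TermMatch", "OboError", "load_obo", "tag_terms", "tag_article"]

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")
_EXACT_SYN_RE = re.compile(r'^"(.*)"\s+EXACT\b')


class OboError(ValueError):
    """Raised when an OBO document cannot be parsed."""


def _normalize(surface: str) -> str:
    """Canonical matching key: lowercase tokens joined by single spaces."""
    return " ".join(t.lower() for t in _TOKEN_RE.findall(surface))


@dataclass(frozen=True)
class TermMatch:
    """One tagged ontology term occurrence; offsets are 0-based half-open
    into the unit text and cover whole tokens."""

    term_id: str
    ontology_name: str
    start: int
    end: int
    matched_text: str


class TermDictionary:
    """Surface-form lookup for one ontology.

    ``entries`` maps the normalized surface form to ``(ontology_name,
    term_id, preferred_name)``; when two terms of one ontology share a
    surface form the lexicographically smallest term id wins, so tagging
    is deterministic.  ``max_term_tokens`` bounds the window the tagger
    slides over the text.
    """

    def __init__(self, ontology_name: str,
                 entries: dict[str, tuple[str, str, str]] | None = None):
        self.ontology_name = ontology_name
        self.entries: dict[str, tuple[str, str, str]] = {}
        self.max_term_tokens = 0
        for surface, (onto, term_id, name) in (entries or {}).items():
            self.add(surface, term_id, name)

    def add(self, surface: str, term_id: str, preferred_name: str) -> None:
        key = _normalize(surface)
        if not key:
            return
        existing = self.entries.get(key)
        if existing is None or term_id < existing[1]:
            self.entries[key] = (self.ontology_name, term_id, preferred_name)
        self.max_term_tokens = max(self.max_term_tokens, len(key.split(" ")))

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> tuple[str, str, str] | None:
        return self.entries.get(_normalize(surface))


def load_obo(document: str, ontology_name: str | None = None) -> TermDictionary:
    """Compile an OBO 1.2 document into a :class:`TermDictionary`.

    One entry is created per term name and per EXACT synonym; obsolete
    terms are skipped; BROAD/NARROW/RELATED synonyms are excluded to keep
    false positives down.  ``ontology_name`` defaults to the document's
    ``ontology:`` header.
    """
    try:
        graph = obonet.read_obo(io.StringIO(document), ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subtypes
        raise OboError(f"unparseable OBO stanza: {exc}") from exc
    if ontology_name is None:
        ontology_name = graph.graph.get("ontology") or graph.graph.get("name") or "ontology"
    dictionary = TermDictionary(ontology_name)
    for term_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            continue
        dictionary.add(name, term_id, name)
        for syn in data.get("synonym", ()):
            m = _EXACT_SYN_RE.match(syn)
            if m:
                dictionary.add(m.group(1), term_id, name)
    return dictionary


def tag_terms(text: str, dictionary: TermDictionary) -> list[TermMatch]:
    """Tag one unit's text against one dictionary, longest match first.

    Scans token start positions left to right; at each position the
    longest matching dictionary entry (in tokens) is emitted and the scan
    resumes after it, so emitted matches never overlap.
    """
    if not dictionary.entries:
        return []
    tokens = list(_TOKEN_RE.finditer(text))
    matches: list[TermMatch] = []
    i = 0
    while i < len(tokens):
        hit = None
        for j in range(min(i + dictionary.max_term_tokens, len(tokens)) - 1, i - 1, -1):
            key = " ".join(t.group().lower() for t in tokens[i:j + 1])
            entry = dictionary.entries.get(key)
            if entry is not None:
                start, end = tokens[i].start(), tokens[j].end()
                hit = TermMatch(term_id=entry[1], ontology_name=entry[0],
                                start=start, end=end, matched_text=text[start:end])
                i = j + 1
                break
        if hit is not None:
            matches.append(hit)
        else:
            i += 1
    return matches


def tag_article(article: Article, dictionaries: list[TermDictionary]) -> dict[str, list[TermMatch]]:
    """Tag every text unit against every ontology.

    Each dictionary is applied independently, so the same span may carry
    one match per ontology (never overlapping matches within one
    ontology).  Per-unit results are ordered by position, then ontology,
    then term id.
    """
    out: dict[str, list[TermMatch]] = {}
    for unit in iter_text_units(article):
        unit_matches: list[TermMatch] = []
        for dictionary in dictionaries:
            unit_matches.extend(tag_terms(unit.text, dictionary))
        unit_matches.sort(key=lambda m: (m.start, m.end, m.ontology_name, m.term_id))
        out[unit.unit_id] = unit_matches
    return out
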