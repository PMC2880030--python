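"""Detection and validation of PDB identifier mentions in article text.

A PDB ID is four characters: a digit 1–9 followed by three alphanumerics
(e.g. ``1HIV``).  Raw pattern matching over free text produces false
positives — years, catalogue numbers, and valid IDs that collide with
other vocabulary (the classic case is ``3DNA``, which names both a PDB
entry and a software package).  The miner therefore applies three layers:

1. a candidate pattern requiring at least one letter (killing year-like
   all-digit tokens) and word boundaries;
2. a validity check against the lexicon of existing PDB IDs;
3. a blacklist of known-ambiguous IDs that are kept only when a structural
   cue term ("PDB", "crystal structure", ...) occurs in the same text unit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .corpus import Article, iter_text_units

__all__ = [
    "DEFAULT_CUE_TERMS",
    "IdLexicon",
    "Mention",
    "LexiconError",
    "find_candidates",
    "validate",
    "apply_blacklist_filter",
    "extract_context",
    "mine_article",
    "mine_corpus",
]

logger = logging.getLogger(__name__)

DEFAULT_CUE_TERMS = (
    "PDB",
    "Protein Data Bank",
    "accession",
    "structure",
    "crystal structure",
)

# Word-bounded 4-char token: digit 1-9 then three alphanumerics, not
# adjacent to another alphanumeric (hyphen/underscore count as boundaries,
# so "PDB:1HIV" and "(1HIV)" match).
_CANDIDATE_RE = re.compile(r"(?<![0-9A-Za-z])[1-9][0-9A-Za-z]{3}(?![0-9A-Za-z])")
_ID_RE = re.compile(r"[1-9][0-9A-Z]{3}\Z")


class LexiconError(ValueError):
    """Raised on an unusable identifier lexicon."""


def _read_id_lines(text: str) -> set[str]:
    ids = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line.upper())
    return ids


@dataclass(frozen=True)
class IdLexicon:
    """The set of valid PDB IDs plus the false-positive blacklist.

    ``blacklist`` members are valid IDs known to collide with other
    vocabulary; their mentions require a ``cue_terms`` hit in the same
    text unit to be accepted.
    """

    valid_ids: frozenset[str]
    blacklist: frozenset[str] = frozenset()
    cue_terms: tuple[str, ...] = DEFAULT_CUE_TERMS

    def __post_init__(self):
        bad = [i for i in self.valid_ids if not _ID_RE.match(i)]
        if bad:
            raise LexiconError(f"ill-formed PDB IDs in lexicon: {sorted(bad)[:5]}")
        if not self.blacklist <= self.valid_ids:
            raise LexiconError("blacklist contains IDs absent from the lexicon")

    @classmethod
    def from_text(cls, lexicon_text: str, blacklist_text: str = "",
                  cue_terms: tuple[str, ...] = DEFAULT_CUE_TERMS) -> "IdLexicon":
        """Build from plain-text listings (one ID per line, ``#`` comments)."""
        return cls(
            valid_ids=frozenset(_read_id_lines(lexicon_text)),
            blacklist=frozenset(_read_id_lines(blacklist_text)),
            cue_terms=tuple(cue_terms),
        )

    @classmethod
    def from_files(cls, lexicon_path, blacklist_path=None,
                   cue_terms: tuple[str, ...] = DEFAULT_CUE_TERMS) -> "IdLexicon":
        with open(lexicon_path) as fh:
            lex = fh.read()
        bl = ""
        if blacklist_path is not None:
            with open(blacklist_path) as fh:
                bl = fh.read()
        return cls.from_text(lex, bl, cue_terms)


@dataclass(frozen=True)
class Mention:
    """One validated PDB ID occurrence in one text unit.

    Offsets are 0-based half-open character positions into the
    whitespace-normalized unit text; ``unit_text[start:end].upper()``
    equals ``pdb_id``.
    """

    pdb_id: str
    pmc_id: str
    unit_id: str
    unit_kind: str
    start: int
    end: int
    context: str = ""
    cue_found: bool = False


def find_candidates(text: str) -> list[tuple[str, int, int]]:
    """Scan plain text for candidate PDB ID tokens.

    A candidate is a maximal word-bounded token of exactly four characters
    whose first character is a digit 1–9 and whose remaining three are
    alphanumeric with at least one letter; all-digit (year-like) tokens
    are never candidates.  Returns ``(token, start, end)`` triples with
    0-based half-open offsets.
    """
    out = []
    for m in _CANDIDATE_RE.finditer(text):
        token = m.group()
        if any(c.isalpha() for c in token[1:]):
            out.append((token, m.start(), m.end()))
    return out


def validate(candidates: list[tuple[str, int, int]], lexicon: IdLexicon,
             pmc_id: str = "", unit_id: str = "", unit_kind: str = "") -> list[Mention]:
    """Keep exactly the candidates whose uppercased token is a valid PDB ID.

    Matching is case-insensitive; the stored ``pdb_id`` is canonical
    uppercase.  An empty lexicon is a configuration error.
    """
    if not lexicon.valid_ids:
        raise LexiconError("empty lexicon: a PDB ID list must be supplied")
    mentions = []
    for token, start, end in candidates:
        pdb_id = token.upper()
        if pdb_id in lexicon.valid_ids:
            mentions.append(Mention(pdb_id=pdb_id, pmc_id=pmc_id, unit_id=unit_id,
                                    unit_kind=unit_kind, start=start, end=end))
    return mentions


def _has_cue(unit_text: str, cue_terms: tuple[str, ...]) -> bool:
    low = unit_text.lower()
    return any(cue.lower() in low for cue in cue_terms)


def apply_blacklist_filter(mentions: list[Mention], unit_text: str,
                           lexicon: IdLexicon) -> list[Mention]:
    """Apply the stricter contextual criteria for blacklisted IDs.

    A mention of a blacklisted ID survives only if a cue term occurs
    (case-insensitively) anywhere in the same text unit.  Non-blacklisted
    mentions pass unchanged.  ``cue_found`` is recorded on every mention.
    Filtered candidates are logged for audit.
    """
    cue = _has_cue(unit_text, lexicon.cue_terms)
    kept = []
    for m in mentions:
        m = replace(m, cue_found=cue)
        if m.pdb_id in lexicon.blacklist and not cue:
            logger.info("blacklist filter dropped %s in %s/%s (no cue term)",
                        m.pdb_id, m.pmc_id, m.unit_id)
            continue
        kept.append(m)
    return kept


def extract_context(article: Article, mention: Mention) -> str:
    """The display context of a mention: the figure legend for caption
    mentions, otherwise the full text of the containing paragraph, abstract
    paragraph or title."""
    return article.unit(mention.unit_id).text


def mine_article(article: Article, lexicon: IdLexicon) -> list[Mention]:
    """Find → validate → blacklist-filter → contextualize, per text unit.

    Deterministic; mentions come out in unit order, then left to right
    within a unit.  Duplicate mentions of one ID in one unit are all
    recorded (deduplication happens at association level).
    """
    out: list[Mention] = []
    for unit in iter_text_units(article):
        cands = find_candidates(unit.text)
        ms = validate(cands, lexicon, article.pmc_id, unit.unit_id, unit.kind)
        ms = apply_blacklist_filter(ms, unit.text, lexicon)
        out.extend(replace(m, context=unit.text) for m in ms)
    return out


def mine_corpus(articles, lexicon: IdLexicon) -> list[Mention]:
    """Mine every article of an iterable; concatenated per-article results."""
    out: list[Mention] = []
    for article in articles:
        out.extend(mine_article(article, lexicon))
    return out
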