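"""Corpus-level driver tying the stages together.

A corpus is a directory of JATS XML files, one article per file.  The
driver parses every article, mines PDB ID mentions against a lexicon and
aggregates them into the association table; the result object is what the
CLI verbs and payload exporters operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .association import AssociationTable, build_associations
from .corpus import Article, parse_jats_file
from .mining import IdLexicon, Mention, mine_article

__all__ = ["MinedCorpus", "load_articles", "mine_directory", "mine_articles"]


@dataclass
class MinedCorpus:
    """Parsed articles, their validated mentions, and the association table."""

    articles: dict[str, Article]
    mentions: list[Mention]
    _table: AssociationTable | None = field(default=None, repr=False)

    @property
    def table(self) -> AssociationTable:
        if self._table is None:
            self._table = build_associations(self.mentions)
        return self._table


def load_articles(corpus_dir) -> dict[str, Article]:
    """Parse every ``*.xml`` file of a corpus directory, keyed by PMC ID,
    in sorted filename order."""
    articles: dict[str, Article] = {}
    for path in sorted(Path(corpus_dir).glob("*.xml")):
        art = parse_jats_file(path)
        articles[art.pmc_id] = art
    return articles


def mine_articles(articles: Iterable[Article], lexicon: IdLexicon) -> MinedCorpus:
    arts = {a.pmc_id: a for a in articles}
    mentions: list[Mention] = []
    for pmc_id in arts:
        mentions.extend(mine_article(arts[pmc_id], lexicon))
    return MinedCorpus(articles=arts, mentions=mentions)


def mine_directory(corpus_dir, lexicon: IdLexicon) -> MinedCorpus:
    return mine_articles(load_articles(corpus_dir).values(), lexicon)
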