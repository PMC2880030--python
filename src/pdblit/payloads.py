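"""Serializable result payloads and annotated-article markup.

The mined corpus is exposed in two file-payload shapes mirroring the
classic structure-literature web services: per-article metadata for all
articles mentioning a given PDB ID, and the figure list of one article.
Payloads serialize to key-sorted JSON so identical inputs produce
byte-identical exports.

``write_markup`` re-emits an article as XML with inline annotation
elements around every PDB mention and ontology term; stripping the
annotations recovers the unit texts byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from lxml import etree

from .association import AssociationTable
from .corpus import Article, iter_text_units
from .mining import Mention
from .ontology import TermMatch

__all__ = [
    "ArticleMetadataPayload",
    "FigureListPayload",
    "export_metadata_for_id",
    "export_figures",
    "write_markup",
    "strip_markup",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArticleMetadataPayload:
    """Literature metadata of one article, restricted to one PDB ID."""

    pmc_id: str
    title: str
    abstract: str
    license_note: str
    mentions: tuple[tuple[str, str, str], ...]  # (pdb_id, unit_kind, context)

    def to_dict(self) -> dict:
        return {
            "pmc_id": self.pmc_id,
            "title": self.title,
            "abstract": self.abstract,
            "license_note": self.license_note,
            "mentions": [
                {"pdb_id": p, "unit_kind": k, "context": c} for p, k, c in self.mentions
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


@dataclass(frozen=True)
class FigureListPayload:
    """All figures of one article, in document order."""

    pmc_id: str
    figures: tuple[tuple[str, str, str, str | None], ...]

    def to_dict(self) -> dict:
        return {
            "pmc_id": self.pmc_id,
            "figures": [
                {"figure_id": f, "label": l, "caption": c, "graphic_ref": g}
                for f, l, c, g in self.figures
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def export_metadata_for_id(table: AssociationTable, articles: Mapping[str, Article],
                           mentions: Iterable[Mention], pdb_id: str,
                           ) -> list[ArticleMetadataPayload]:
    """One metadata payload per article mentioning *pdb_id*, ordered by
    PMC ID; an unknown ID yields an empty list (a valid structure simply
    unmentioned in the corpus)."""
    pdb_id = pdb_id.upper()
    wanted = table.by_id.get(pdb_id, {})
    per_article: dict[str, list[tuple[str, str, str]]] = {p: [] for p in wanted}
    for m in mentions:
        if m.pdb_id == pdb_id and m.pmc_id in per_article:
            per_article[m.pmc_id].append((m.pdb_id, m.unit_kind, m.context))
    out = []
    for pmc_id in sorted(per_article):
        art = articles[pmc_id]
        out.append(ArticleMetadataPayload(
            pmc_id=pmc_id,
            title=art.title,
            abstract=art.abstract,
            license_note=art.copyright_note,
            mentions=tuple(per_article[pmc_id]),
        ))
    return out


def export_figures(article: Article) -> FigureListPayload:
    """The figure list of one article, captions verbatim from the parse."""
    return FigureListPayload(
        pmc_id=article.pmc_id,
        figures=tuple((f.figure_id, f.label, f.caption, f.graphic_ref)
                      for f in article.figures),
    )


def _resolve_spans(unit_id: str, mentions: list[Mention], terms: list[TermMatch]):
    """Merge mention and term spans into non-overlapping annotation groups.

    A PDB mention always wins against an overlapping term (the term is
    dropped and logged); terms from different ontologies covering the
    *identical* span are nested; partially overlapping terms keep the
    first in (start, end, ontology, term) order.
    Returns groups of (start, end, [("mention"|"term", payload), ...]).
    """
    groups: list[tuple[int, int, list]] = []
    for m in sorted(mentions, key=lambda m: m.start):
        groups.append((m.start, m.end, [("mention", m)]))
    for t in sorted(terms, key=lambda t: (t.start, t.end, t.ontology_name, t.term_id)):
        clash = None
        for g in groups:
            if t.start < g[1] and g[0] < t.end:  # overlap
                clash = g
                break
        if clash is None:
            groups.append((t.start, t.end, [("term", t)]))
        elif (clash[0], clash[1]) == (t.start, t.end) and clash[2][0][0] == "term":
            clash[2].append(("term", t))
        else:
            logger.info("dropped term %s overlapping annotation in unit %s",
                        t.term_id, unit_id)
    groups.sort(key=lambda g: g[0])
    return groups


def write_markup(article: Article, mentions: Iterable[Mention],
                 term_matches: Mapping[str, list[TermMatch]] | None = None) -> str:
    """Emit the article as annotated XML.

    Every text unit becomes a ``<unit>`` element whose mention spans are
    wrapped in ``<mention pdb="...">`` and term spans in
    ``<term ontology="..." term="...">``.  Stripping all annotation
    elements recovers each unit text byte-identically.
    """
    term_matches = term_matches or {}
    by_unit: dict[str, list[Mention]] = {}
    for m in mentions:
        by_unit.setdefault(m.unit_id, []).append(m)

    root = etree.Element("annotated-article")
    root.set("pmc-id", article.pmc_id)
    for unit in iter_text_units(article):
        unit_el = etree.SubElement(root, "unit")
        unit_el.set("id", unit.unit_id)
        unit_el.set("kind", unit.kind)
        groups = _resolve_spans(unit.unit_id, by_unit.get(unit.unit_id, []),
                                term_matches.get(unit.unit_id, []))
        pos = 0
        prev_el = None
        for start, end, anns in groups:
            gap = unit.text[pos:start]
            if prev_el is None:
                unit_el.text = (unit_el.text or "") + gap
            else:
                prev_el.tail = (prev_el.tail or "") + gap
            parent = unit_el
            innermost = None
            for kind, payload in anns:
                if kind == "mention":
                    el = etree.SubElement(parent, "mention")
                    el.set("pdb", payload.pdb_id)
                else:
                    el = etree.SubElement(parent, "term")
                    el.set("ontology", payload.ontology_name)
                    el.set("term", payload.term_id)
                parent = el
                innermost = el
            innermost.text = unit.text[start:end]
            prev_el = unit_el[-1]
            pos = end
        tail = unit.text[pos:]
        if prev_el is None:
            unit_el.text = (unit_el.text or "") + tail
        else:
            prev_el.tail = (prev_el.tail or "") + tail
    return etree.tostring(root, encoding="unicode")


def strip_markup(markup_xml: str) -> dict[str, str]:
    """Recover ``{unit_id: text}`` from annotated XML by dropping all
    annotation elements."""
    root = etree.fromstring(markup_xml.encode("utf-8"))
    return {u.get("id"): "".join(u.itertext()) for u in root.iter("unit")}
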