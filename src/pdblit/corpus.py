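"""Parsing of NLM/JATS full-text article XML into a minable article model.

PubMed Central distributes open-access articles as XML conforming to the
NLM DTD (2.x) or its successor JATS (1.x).  This module reduces such a
document to the units of text a literature miner cares about: the title,
the abstract paragraphs, the body paragraphs and the figure captions.
Reference lists and tables are deliberately ignored — the point of mining
full text is to find identifier mentions *outside* the formal citation
apparatus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from lxml import etree

__all__ = [
    "Article",
    "TextUnit",
    "Figure",
    "JatsParseError",
    "parse_jats",
    "parse_jats_file",
    "iter_text_units",
]

# Inline formatting and cross-reference elements are flattened to their
# text content; these are the common NLM 2.x / JATS 1.x inline tags.
_SKIP_SUBTREES = frozenset({"table-wrap", "table", "ref-list", "disp-formula"})

_WS_RE = re.compile(r"\s+")

_XLINK = "{http://www.w3.org/1999/xlink}href"


class JatsParseError(ValueError):
    """Raised when a document cannot be parsed as a JATS/NLM article."""


@dataclass(frozen=True)
class TextUnit:
    """One minable unit of plain text within an article.

    ``kind`` is one of ``title``, ``abstract_para``, ``body_para`` or
    ``caption``; ``section_path`` holds the titles of enclosing sections
    (empty for title/abstract units); ``text`` is markup-free with runs of
    whitespace collapsed to single spaces.
    """

    unit_id: str
    kind: str
    section_path: tuple[str, ...]
    text: str


@dataclass(frozen=True)
class Figure:
    figure_id: str
    label: str
    caption: str
    graphic_ref: str | None = None


@dataclass
class Article:
    """Structured representation of one full-text article."""

    pmc_id: str
    title: str
    abstract_units: list[TextUnit] = field(default_factory=list)
    body_units: list[TextUnit] = field(default_factory=list)
    figures: list[Figure] = field(default_factory=list)
    copyright_note: str = ""

    @property
    def abstract(self) -> str:
        return " ".join(u.text for u in self.abstract_units)

    @property
    def title_unit(self) -> TextUnit:
        return TextUnit("title", "title", (), self.title)

    def unit(self, unit_id: str) -> TextUnit:
        for u in iter_text_units(self):
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no text unit {unit_id!r} in article {self.pmc_id}")


def _flatten(elem: etree._Element) -> str:
    """Text content of *elem* with markup stripped and whitespace collapsed.

    Descends into unrecognized elements (lenient across DTD versions) but
    skips excluded subtrees such as tables.
    """
    parts: list[str] = []

    def walk(e: etree._Element) -> None:
        tag = e.tag if isinstance(e.tag, str) else ""
        local = etree.QName(tag).localname if tag else ""
        if local in _SKIP_SUBTREES:
            if e.tail:
                parts.append(e.tail)
            return
        if e.text:
            parts.append(e.text)
        for child in e:
            walk(child)
        if e.tail:
            parts.append(e.tail)

    if elem.text:
        parts.append(elem.text)
    for child in elem:
        walk(child)
    return _WS_RE.sub(" ", "".join(parts)).strip()


def _find_pmc_id(root: etree._Element) -> str:
    for aid in root.iter("article-id"):
        if aid.get("pub-id-type") in ("pmc", "pmcid"):
            text = (aid.text or "").strip()
            if text:
                return text.removeprefix("PMC")
    raise JatsParseError("no pmc id: document carries no <article-id pub-id-type='pmc'>")


def _paragraphs(elem: etree._Element, section_path: tuple[str, ...]) -> Iterator[tuple[tuple[str, ...], etree._Element]]:
    """Yield (section_path, <p> element) for paragraphs under *elem* in
    document order, descending into <sec> and unknown wrappers, skipping
    figures, tables and reference lists."""
    for child in elem:
        tag = child.tag if isinstance(child.tag, str) else None
        if tag is None:
            continue
        local = etree.QName(tag).localname
        if local == "p":
            yield section_path, child
        elif local == "sec":
            title_el = child.find("title")
            title = _flatten(title_el) if title_el is not None else ""
            sub = section_path + (title,) if title else section_path
            yield from _paragraphs(child, sub)
        elif local in ("fig", "fig-group") or local in _SKIP_SUBTREES:
            continue
        elif local in ("boxed-text", "disp-quote", "list", "list-item"):
            yield from _paragraphs(child, section_path)
        # other element kinds (title, label, graphic ...) carry no body paragraphs


def _parse_figure(fig: etree._Element, index: int) -> Figure:
    figure_id = fig.get("id") or f"fig-{index}"
    label_el = fig.find("label")
    label = _flatten(label_el) if label_el is not None else ""
    caption_el = fig.find("caption")
    caption = _flatten(caption_el) if caption_el is not None else ""
    graphic_ref = None
    for g in fig.iter("graphic"):
        graphic_ref = g.get(_XLINK) or g.get("href")
        if graphic_ref:
            break
    return Figure(figure_id=figure_id, label=label, caption=caption, graphic_ref=graphic_ref)


def parse_jats(document: str | bytes) -> Article:
    """Parse a JATS/NLM article document into an :class:`Article`.

    Accepts both NLM 2.x and JATS 1.x tag vocabularies.  Inline formatting
    (italic, bold, sub, sup) and cross-references are flattened to their
    display text; tables and reference lists are excluded from text units.

    Raises :class:`JatsParseError` on malformed XML (naming the offending
    line) or when the document carries no PMC identifier.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise JatsParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc

    pmc_id = _find_pmc_id(root)

    title_el = root.find(".//article-title")
    title = _flatten(title_el) if title_el is not None else ""

    abstract_units: list[TextUnit] = []
    meta = root.find(".//article-meta")
    abstract_el = meta.find("abstract") if meta is not None else root.find(".//abstract")
    if abstract_el is not None:
        paras = [p for _, p in _paragraphs(abstract_el, ())]
        if not paras and _flatten(abstract_el):
            # abstract with bare text, no <p> wrapper
            abstract_units.append(TextUnit("abs-1", "abstract_para", (), _flatten(abstract_el)))
        for i, p in enumerate(paras, 1):
            text = _flatten(p)
            if text:
                abstract_units.append(TextUnit(f"abs-{i}", "abstract_para", (), text))

    copyright_note = ""
    for tag in ("copyright-statement", "license-p"):
        el = root.find(f".//{tag}")
        if el is not None:
            copyright_note = _flatten(el)
            break

    body_units: list[TextUnit] = []
    body = root.find("body")
    if body is not None:
        for i, (path, p) in enumerate(_paragraphs(body, ()), 1):
            text = _flatten(p)
            if text:
                body_units.append(TextUnit(f"p-{i}", "body_para", path, text))

    figures: list[Figure] = []
    for i, fig in enumerate(root.iter("fig"), 1):
        figures.append(_parse_figure(fig, i))
    for fig in figures:
        body_units.append(TextUnit(f"cap-{fig.figure_id}", "caption", (), fig.caption))

    return Article(
        pmc_id=pmc_id,
        title=title,
        abstract_units=abstract_units,
        body_units=body_units,
        figures=figures,
        copyright_note=copyright_note,
    )


def parse_jats_file(path) -> Article:
    with open(path, "rb") as fh:
        return parse_jats(fh.read())


def iter_text_units(article: Article) -> list[TextUnit]:
    """All minable text units: title, abstract paragraphs, body paragraphs
    in document order, then figure captions in figure order."""
    return [article.title_unit, *article.abstract_units, *article.body_units]
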