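"""Synthetic JATS corpora, ontologies, lexicons and chain FASTA with exact
ground truth.

Every stage of the mining pipeline is testable without downloading a
single article: this module emits well-formed JATS XML with PDB IDs,
decoy tokens and ontology terms planted at known offsets, together with a
machine-readable truth manifest.  Ground truth is exact by construction —
the filler vocabulary contains no pattern-conformant 4-character tokens
(every filler word is purely alphabetic, and a candidate must start with
a digit), no cue terms, and no ontology-term words, so nothing can match
except what was planted.

Planted tokens come in the flavors the miner must discriminate:

* valid lexicon IDs in ordinary prose (must be recovered);
* blacklisted IDs next to a cue term such as "PDB" (must be recovered);
* blacklisted IDs with no cue in the unit (must be filtered);
* year-like all-digit tokens (never candidates);
* pattern-conformant tokens absent from the lexicon (rejected by the
  validity check).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .mining import IdLexicon

__all__ = [
    "PlantSpec",
    "PlantedMention",
    "PlantedTerm",
    "Decoy",
    "ArticleTruth",
    "TruthManifest",
    "generate_lexicon",
    "generate_corpus",
    "write_corpus",
    "generate_obo",
    "generate_chain_fasta",
]

# Filler words: purely alphabetic, free of cue-term substrings ("pdb",
# "structure", "accession", "crystal", "protein"/"data"/"bank") and
# disjoint from the ontology-term vocabulary below.
_FILLER = (
    "the measured signal confirms that binding occurs rapidly under mild "
    "conditions and the refined model reveals a deep pocket near the long "
    "flexible loop while earlier assays indicated weak affinity for small "
    "ligands suggesting that conserved residues stabilize the fold through "
    "polar contacts and buried interfaces observed across related families "
    "moreover kinetic experiments showed slow exchange within the core "
    "region whereas surface segments remained mobile during simulation"
).split()

# Vocabulary reserved for synthetic ontology term names.
_TERM_WORDS = (
    "zinc finger helix barrel kinase domain motif transferase receptor "
    "channel membrane ribosome polymerase hydrolase ligase isomerase sheet "
    "coil turn bundle clamp lobe groove hinge propeller solenoid hairpin "
    "oxidase reductase synthase protease esterase lectin porin globin "
    "repressor activator operon codon intron exon promoter enhancer histone "
    "nucleosome chaperone ubiquitin proteasome flagellum pilus capsid virion"
).split()

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_PLAIN_TEMPLATES = [
    ("The refined model", "reveals a deep catalytic pocket near the rim."),
    ("Binding assays involving", "showed slow exchange within the core region."),
    ("The entry", "was compared against earlier refined models."),
    ("Residues surrounding", "remain mobile during the simulation."),
]
_CUE_TEMPLATES = [
    ("The PDB entry", "shows a bent ridge across the interface."),
    ("As deposited in the Protein Data Bank,", "represents the ligand-bound state."),
    ("The crystal structure", "was solved at high resolution."),
]
_YEAR_TEMPLATES = [
    ("The assay was first described in", "by the same consortium."),
    ("Samples collected during", "were re-examined later."),
]
_FAKE_TEMPLATES = [
    ("The sample batch", "was discarded after the review."),
    ("Catalogue item", "refers to a reagent kit."),
]


class SpecError(ValueError):
    """Raised on an impossible generation specification."""


@dataclass(frozen=True)
class PlantSpec:
    """Knobs of one synthetic corpus; generation is a pure function of
    (spec, lexicon, terms).

    Per-article ranges are inclusive ``(lo, hi)``.  The defaults produce,
    per 100 articles, roughly 300 recoverable planted mentions and 150
    decoy tokens (years, non-lexicon IDs, cue-less blacklisted IDs).
    """

    n_articles: int = 100
    ids_per_article: tuple[int, int] = (2, 4)
    years_per_article: tuple[int, int] = (0, 1)
    fake_ids_per_article: tuple[int, int] = (0, 1)
    blacklist_decoys_per_article: tuple[int, int] = (0, 1)
    blacklist_true_per_article: tuple[int, int] = (0, 1)
    terms_per_article: tuple[int, int] = (0, 3)
    double_mention_rate: float = 0.2
    caption_rate: float = 0.25
    seed: int = 0


@dataclass(frozen=True)
class PlantedMention:
    pdb_id: str
    unit_id: str
    unit_kind: str
    start: int
    end: int
    blacklisted: bool = False
    cue: bool = False


@dataclass(frozen=True)
class PlantedTerm:
    term_id: str
    ontology: str
    unit_id: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class Decoy:
    token: str
    kind: str  # "year" | "fake_id" | "blacklist_no_cue"
    unit_id: str


@dataclass
class ArticleTruth:
    pmc_id: str
    unit_texts: dict[str, str]
    mentions: list[PlantedMention] = field(default_factory=list)
    decoys: list[Decoy] = field(default_factory=list)
    terms: list[PlantedTerm] = field(default_factory=list)


@dataclass
class TruthManifest:
    articles: list[ArticleTruth] = field(default_factory=list)

    @property
    def n_mentions(self) -> int:
        return sum(len(a.mentions) for a in self.articles)

    @property
    def n_decoys(self) -> int:
        return sum(len(a.decoys) for a in self.articles)

    def expected_associations(self) -> dict[str, dict[str, int]]:
        """Per-ID article mention counts implied by the planted mentions."""
        out: dict[str, dict[str, int]] = {}
        for art in self.articles:
            for m in art.mentions:
                out.setdefault(m.pdb_id, {})
                out[m.pdb_id][art.pmc_id] = out[m.pdb_id].get(art.pmc_id, 0) + 1
        return out


def _random_pdb_id(rng: random.Random) -> str:
    while True:
        token = rng.choice("123456789") + "".join(
            rng.choice(string.ascii_uppercase + string.digits) for _ in range(3))
        if any(c.isalpha() for c in token[1:]):
            return token


def generate_lexicon(n_ids: int = 200, n_blacklist: int = 5, seed: int = 0) -> IdLexicon:
    """A synthetic PDB ID lexicon with a blacklist subset."""
    rng = random.Random(seed)
    ids: set[str] = set()
    while len(ids) < n_ids:
        ids.add(_random_pdb_id(rng))
    blacklist = frozenset(rng.sample(sorted(ids), min(n_blacklist, n_ids)))
    return IdLexicon(valid_ids=frozenset(ids), blacklist=blacklist)


class _UnitBuilder:
    """Accumulates space-joined text while tracking planted-token offsets."""

    def __init__(self):
        self._parts: list[str] = []
        self._len = 0

    def add(self, piece: str) -> tuple[int, int]:
        if self._len:
            self._len += 1  # joining space
        start = self._len
        self._parts.append(piece)
        self._len += len(piece)
        return start, self._len

    @property
    def text(self) -> str:
        return " ".join(self._parts)


def _filler_sentence(rng: random.Random, n_lo: int = 5, n_hi: int = 10) -> str:
    words = [rng.choice(_FILLER) for _ in range(rng.randint(n_lo, n_hi))]
    return words[0].capitalize() + " " + " ".join(words[1:]) + "."


def _plant_sentence(builder: _UnitBuilder, rng: random.Random, token: str,
                    templates, twice: bool = False) -> list[tuple[int, int]]:
    head, tail = rng.choice(templates)
    builder.add(head)
    spans = [builder.add(token)]
    if twice:
        builder.add("and its duplicate entry")
        spans.append(builder.add(token))
    builder.add(tail)
    return spans


def _randint(rng: random.Random, bounds: tuple[int, int]) -> int:
    return rng.randint(*bounds)


def generate_corpus(spec: PlantSpec, lexicon: IdLexicon,
                    terms: list[tuple[str, str, str]] | None = None,
                    ) -> tuple[dict[str, str], TruthManifest]:
    """Emit a synthetic JATS corpus and its truth manifest.

    ``terms`` is an optional list of ``(term_id, ontology_name, surface)``
    plantable ontology terms (e.g. from :func:`generate_obo`'s manifest).
    Returns ``{filename: xml_text}`` plus the manifest; deterministic per
    spec (the seed lives inside the spec).
    """
    rng = random.Random(spec.seed)
    plantable = sorted(lexicon.valid_ids - lexicon.blacklist)
    blacklisted = sorted(lexicon.blacklist)
    if spec.ids_per_article[1] > len(plantable):
        raise SpecError("ids_per_article exceeds the number of non-blacklisted lexicon IDs")
    if (spec.blacklist_decoys_per_article[1] or spec.blacklist_true_per_article[1]) and not blacklisted:
        raise SpecError("blacklist plants requested but the lexicon has no blacklist")

    files: dict[str, str] = {}
    manifest = TruthManifest()

    for a_idx in range(spec.n_articles):
        pmc_id = str(100001 + a_idx)
        truth = ArticleTruth(pmc_id=pmc_id, unit_texts={})

        title = _filler_sentence(rng, 4, 7).rstrip(".")
        abstract = _filler_sentence(rng) + " " + _filler_sentence(rng)
        truth.unit_texts["title"] = title
        truth.unit_texts["abs-1"] = abstract

        # one payload per unit so cue terms can never leak into decoy units
        payloads: list[tuple[str, ...]] = []
        for _ in range(_randint(rng, spec.ids_per_article)):
            payloads.append(("mention", rng.choice(plantable)))
        for _ in range(_randint(rng, spec.blacklist_true_per_article)):
            payloads.append(("blacklist_cue", rng.choice(blacklisted)))
        for _ in range(_randint(rng, spec.blacklist_decoys_per_article)):
            payloads.append(("blacklist_no_cue", rng.choice(blacklisted)))
        for _ in range(_randint(rng, spec.years_per_article)):
            payloads.append(("year", str(rng.randint(1900, 2030))))
        for _ in range(_randint(rng, spec.fake_ids_per_article)):
            while True:
                fake = _random_pdb_id(rng)
                if fake not in lexicon.valid_ids:
                    break
            payloads.append(("fake_id", fake))
        if terms:
            for _ in range(_randint(rng, spec.terms_per_article)):
                payloads.append(("term", *rng.choice(terms)))
        rng.shuffle(payloads)

        body_paras: list[str] = []   # body paragraph texts in order
        captions: list[str] = []     # figure caption texts in order

        def build_unit(payload: tuple[str, ...] | None, as_caption: bool) -> tuple[str, str]:
            """Returns (unit_id, text); registers truth entries."""
            b = _UnitBuilder()
            if not as_caption:
                b.add(_filler_sentence(rng))
            if payload is not None:
                kind = payload[0]
                if kind in ("mention", "blacklist_cue", "blacklist_no_cue"):
                    token = payload[1]
                    templates = _CUE_TEMPLATES if kind == "blacklist_cue" else _PLAIN_TEMPLATES
                    twice = kind == "mention" and rng.random() < spec.double_mention_rate
                    spans = _plant_sentence(b, rng, token, templates, twice)
                elif kind == "year":
                    spans = _plant_sentence(b, rng, payload[1], _YEAR_TEMPLATES)
                elif kind == "fake_id":
                    spans = _plant_sentence(b, rng, payload[1], _FAKE_TEMPLATES)
                else:  # term
                    _, term_id, onto, surface = payload
                    b.add("Here the")
                    spans = [b.add(surface)]
                    b.add("region is clearly visible.")
            b.add(_filler_sentence(rng, 4, 8))

            if as_caption:
                fig_id = f"F{len(captions) + 1}"
                unit_id, unit_kind = f"cap-{fig_id}", "caption"
                captions.append(b.text)
            else:
                unit_id, unit_kind = f"p-{len(body_paras) + 1}", "body_para"
                body_paras.append(b.text)

            if payload is not None:
                kind = payload[0]
                if kind == "mention":
                    for s, e in spans:
                        truth.mentions.append(PlantedMention(
                            payload[1], unit_id, unit_kind, s, e))
                elif kind == "blacklist_cue":
                    for s, e in spans:
                        truth.mentions.append(PlantedMention(
                            payload[1], unit_id, unit_kind, s, e,
                            blacklisted=True, cue=True))
                elif kind == "blacklist_no_cue":
                    truth.decoys.append(Decoy(payload[1], "blacklist_no_cue", unit_id))
                elif kind in ("year", "fake_id"):
                    truth.decoys.append(Decoy(payload[1], kind, unit_id))
                else:
                    _, term_id, onto, surface = payload
                    s, e = spans[0]
                    truth.terms.append(PlantedTerm(term_id, onto, unit_id, s, e, surface))
            truth.unit_texts[unit_id] = b.text
            return unit_id, b.text

        # a leading plain filler paragraph, then one unit per payload
        build_unit(None, as_caption=False)
        for payload in payloads:
            as_caption = (payload[0] in ("mention", "blacklist_cue", "blacklist_no_cue")
                          and rng.random() < spec.caption_rate)
            build_unit(payload, as_caption)

        files[f"PMC{pmc_id}.xml"] = _render_jats(pmc_id, title, abstract, body_paras,
                                                 captions, rng)
        manifest.articles.append(truth)

    return files, manifest


def _render_jats(pmc_id: str, title: str, abstract: str, body_paras: list[str],
                 captions: list[str], rng: random.Random) -> str:
    """Serialize one article as NLM/JATS XML.

    Occasionally wraps a word in <italic> to exercise inline flattening
    downstream; the flattened text is unchanged because the parser strips
    inline markup.
    """
    def maybe_italicize(text: str) -> str:
        words = text.split(" ")
        if len(words) > 3 and rng.random() < 0.3:
            # only decorate pure filler words, never planted tokens
            k = next((i for i, w in enumerate(words) if w.isalpha() and w.islower()), None)
            if k is not None:
                words[k] = f"<italic>{escape(words[k])}</italic>"
                return " ".join(escape(w) if i != k else w for i, w in enumerate(words))
        return escape(text)

    paras = "\n".join(f"      <p>{maybe_italicize(t)}</p>" for t in body_paras)
    figs = "\n".join(
        f'    <fig id="F{i}"><label>Figure {i}</label>'
        f"<caption><p>{maybe_italicize(t)}</p></caption>"
        f'<graphic xlink:href="g{i}.jpg"/></fig>'
        for i, t in enumerate(captions, 1)
    )
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<article xmlns:xlink="http://www.w3.org/1999/xlink" article-type="research-article">
  <front>
    <article-meta>
      <article-id pub-id-type="pmc">{pmc_id}</article-id>
      <title-group><article-title>{escape(title)}</article-title></title-group>
      <abstract><p>{escape(abstract)}</p></abstract>
      <permissions><copyright-statement>Open access under synthetic license.</copyright-statement></permissions>
    </article-meta>
  </front>
  <body>
    <sec>
      <title>Results</title>
{paras}
    </sec>
{figs}
  </body>
  <back>
    <ref-list>
      <ref id="B1"><mixed-citation>A reference mentioning 9XYZ that must be ignored.</mixed-citation></ref>
    </ref-list>
  </back>
</article>
"""


def write_corpus(files: dict[str, str], out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(files):
        p = out / name
        p.write_text(files[name], encoding="utf-8")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Synthetic ontologies
# ---------------------------------------------------------------------------

def generate_obo(n_terms: int, synonym_rate: float = 0.3, seed: int = 0,
                 ontology_name: str = "synthont", obsolete_extra: int = 0,
                 ) -> tuple[str, list[dict]]:
    """A valid OBO 1.2 document of *n_terms* live terms plus a manifest.

    Multi-word term names are generated with deliberate nesting (for some
    terms a sibling term extends it by one token) to exercise the
    longest-match rule.  ``obsolete_extra`` appends obsolete stanzas that
    a loader must skip; they are not in the manifest.  The manifest is a
    list of ``{"id", "name", "synonyms"}`` dicts.
    """
    rng = random.Random(seed)
    surfaces_used: set[str] = set()

    def fresh_surface(n_tokens: int) -> str:
        # escalate to longer surfaces once a token count is exhausted
        while n_tokens <= 5:
            for _ in range(200):
                s = " ".join(rng.choice(_TERM_WORDS) for _ in range(n_tokens))
                if s not in surfaces_used:
                    surfaces_used.add(s)
                    return s
            n_tokens += 1
        raise SpecError("term vocabulary exhausted; lower n_terms")

    manifest: list[dict] = []
    names: list[str] = []
    i = 0
    while len(manifest) < n_terms:
        i += 1
        term_id = f"SYNT:{i:07d}"
        prev_multi = [n for n in names if " " in n]
        if prev_multi and rng.random() < 0.3:
            base = rng.choice(prev_multi)
            name = base + " " + rng.choice(_TERM_WORDS)
            if name in surfaces_used:
                name = fresh_surface(rng.randint(1, 3))
            else:
                surfaces_used.add(name)
        else:
            name = fresh_surface(rng.randint(1, 3))
        synonyms = []
        if rng.random() < synonym_rate:
            synonyms.append(fresh_surface(rng.randint(1, 2)))
        manifest.append({"id": term_id, "name": name, "synonyms": synonyms})
        names.append(name)

    stanzas = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for entry in manifest:
        stanzas.append("[Term]")
        stanzas.append(f"id: {entry['id']}")
        stanzas.append(f"name: {entry['name']}")
        for syn in entry["synonyms"]:
            stanzas.append(f'synonym: "{syn}" EXACT []')
        stanzas.append("")
    for j in range(obsolete_extra):
        stanzas.append("[Term]")
        stanzas.append(f"id: SYNT:{9000000 + j:07d}")
        stanzas.append(f"name: obsolete {fresh_surface(1)} {j}")
        stanzas.append("is_obsolete: true")
        stanzas.append("")
    return "\n".join(stanzas), manifest


def plantable_terms(manifest: list[dict], ontology_name: str = "synthont",
                    ) -> list[tuple[str, str, str]]:
    """Flatten an OBO manifest to ``(term_id, ontology, surface)`` plants.

    Every surface (name or exact synonym) is safe to plant: a longer
    dictionary entry could only swallow a planted surface if the text
    *after* it continued that longer term, and the filler vocabulary is
    disjoint from the term vocabulary, so greedy longest-match always
    recovers exactly the planted surface.
    """
    plants = []
    for entry in manifest:
        for surface in [entry["name"], *entry["synonyms"]]:
            plants.append((entry["id"], ontology_name, surface))
    return plants


# ---------------------------------------------------------------------------
# Synthetic chain FASTA
# ---------------------------------------------------------------------------

def generate_chain_fasta(n_entries: int, chains_per_entry: int = 2,
                         mutation_rate: float = 0.1, seed: int = 0,
                         length: int = 200,
                         pdb_ids: list[str] | None = None,
                         ) -> tuple[str, dict]:
    """Chain sequences for *n_entries* synthetic PDB entries, FASTA text
    plus an identity manifest.

    All chains descend from one random ancestor by independent point
    mutations at the given per-site rate, so the expected identity of any
    chain to the ancestor is ``100 × (1 − mutation_rate)`` and the true
    mutation count of each chain is recorded exactly.  Headers follow the
    ``PDBID_CHAIN`` convention.
    """
    if not 0 <= mutation_rate <= 1:
        raise SpecError("mutation_rate must lie in [0, 1]")
    rng = random.Random(seed)
    ancestor = "".join(rng.choice(_AA20) for _ in range(length))
    if pdb_ids is None:
        pdb_ids = []
        seen = set()
        while len(pdb_ids) < n_entries:
            t = _random_pdb_id(rng)
            if t not in seen:
                seen.add(t)
                pdb_ids.append(t)
    elif len(pdb_ids) < n_entries:
        raise SpecError("not enough pdb_ids supplied")

    chain_ids = string.ascii_uppercase
    lines: list[str] = []
    manifest: dict = {"ancestor": ancestor, "length": length,
                      "mutation_rate": mutation_rate, "chains": {}}
    for pdb_id in pdb_ids[:n_entries]:
        for c in range(chains_per_entry):
            chain = chain_ids[c]
            seq = list(ancestor)
            n_mut = 0
            for pos in range(length):
                if rng.random() < mutation_rate:
                    alt = rng.choice([x for x in _AA20 if x != seq[pos]])
                    seq[pos] = alt
                    n_mut += 1
            seq_s = "".join(seq)
            lines.append(f">{pdb_id}_{chain}")
            for k in range(0, length, 60):
                lines.append(seq_s[k:k + 60])
            manifest["chains"][f"{pdb_id}_{chain}"] = {"mutations": n_mut, "sequence": seq_s}
    return "\n".join(lines) + "\n", manifest
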