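# Methods

## The mining problem

PDB accessions are four characters — a digit 1–9 followed by three
alphanumerics — which makes them unusually hostile to text mining: the
token space collides with years, reagent catalogue numbers and ordinary
abbreviations, and some genuine accessions double as product names
(`3DNA` names a PDB entry, a nucleic-acid analysis package and a wet-lab
kit). `pdblit` treats the problem as a three-stage filter, each stage
auditable on its own:

1. **Candidate pattern.** A candidate is a maximal word-bounded token of
   exactly four characters, first character a digit 1–9, remaining three
   alphanumeric with at least one letter. The letter requirement removes
   all-digit tokens (years) outright; the leading-zero exclusion matches
   the real accession space. "Word-bounded" means not adjacent to an
   alphanumeric character, so punctuation, hyphens and underscores count
   as boundaries and `PDB:1HIV` or `(1HIV)` match. The pattern is a
   declared, configurable rule rather than a learned heuristic: every
   downstream number depends on it, so it must be auditable.
2. **Validity check.** Case-insensitive membership in the lexicon of
   existing PDB IDs (plain text, one ID per line, `#` comments); the
   canonical stored form is uppercase.
3. **Blacklist with contextual cues.** IDs on the blacklist — valid
   accessions known to collide with other vocabulary — are kept only
   when a cue term occurs, case-insensitively, anywhere in the same text
   unit. The shipped cue list is `PDB`, `Protein Data Bank`,
   `accession`, `structure`, `crystal structure`; both lists are
   configuration. Same-unit co-occurrence was chosen over
   sentence-window or distance rules because it is the simplest
   criterion whose effect a curator can verify by reading one paragraph;
   every filtered candidate is logged with its unit id.

Offsets are 0-based, half-open, measured on the whitespace-normalized
unit text, everywhere. Duplicate mentions of one ID in a unit are all
recorded; deduplication happens only at the association level, so
mention counts stay available downstream.

## Text units

A JATS/NLM article is reduced to title, abstract paragraphs, body
paragraphs (document order) and figure captions (figure order). Inline
formatting and cross-references are flattened to their display text;
whitespace runs collapse to single spaces so offsets are stable across
pretty-printed XML. Tables and reference lists are excluded: the value
of full-text mining is precisely finding mentions outside the formal
citation apparatus, and a reference-list hit carries no context worth
extracting. Both NLM 2.x and JATS 1.x tag names are accepted, and
unrecognized wrapper elements are descended into rather than rejected,
because archived PMC content spans DTD generations. Supplementary
sections and PDF/OCR input are out of scope.

A mention's *context* is the full text of its containing unit — the
surrounding paragraph, or the figure legend for caption mentions.

## Ontology tagging

OBO 1.2 ontologies are compiled into per-ontology surface dictionaries:
one entry per term name and per EXACT synonym, obsolete terms skipped.
BROAD/NARROW/RELATED synonyms are excluded — they are where dictionary
taggers leak precision. Surfaces and text are normalized identically:
tokens are maximal alphanumeric runs, lowercased, joined by single
spaces, so `Zinc-Finger` and `zinc finger` meet at the same key and no
term can fire inside a longer word (`cat` never matches in
`catalysis`). No stemming or plural folding is applied.

Tagging scans token start positions left to right; at each position the
longest matching entry (in tokens) is emitted and the scan resumes after
it. Because matching is token-aligned, the paper-facing tie dimensions
(character length at equal token count) collapse: one start position and
one token count determine one span and one dictionary key; residual
collisions between terms sharing a surface within one ontology are
resolved at load time toward the lexicographically smallest term id.
Dictionaries from different ontologies are applied independently, so one
span may carry one match per ontology, but matches within an ontology
never overlap.

## Associations, co-occurrence, sequence identity

Mentions aggregate into `by_id : pdb_id → {article → mention count}` and
its transpose `by_article`. Ranking counts *distinct articles*, not
total mentions, ties broken lexicographically. Co-occurring IDs for a
target are every other ID sharing at least one article, sorted by number
of shared articles then lexicographically.

Co-occurring pairs are annotated with percent identity from a global
Needleman–Wunsch alignment with match +1, mismatch −1, linear gap −1.
Identity is defined as matching columns divided by **all** alignment
columns, gap columns included — conventions differ, so the denominator
is stated and tested. Traceback ties are broken by preferring diagonal,
then up, then left, which pins down one reported alignment; the identity
value of that reported alignment is the contract (alternative optimal
alignments may have different identities). The implementation is an
exact O(nm) dynamic program — at chain-sequence scale there is no need
for heuristic search — and the optimal score is cross-checked in the
test suite against an independent aligner and against exhaustive
alignment enumeration. For multi-chain entries the chain cross-product
is scanned and the best pair reported, ties toward the lexicographically
smallest chain pair. Scoring parameters are exposed as the single place
a different similarity convention would plug in; structure-based
similarity and precomputed sequence clusters are out of scope. Chain
sequences arrive as FASTA with `PDBID_CHAIN` headers; the tool never
fetches or parses structure files.

## Exports

Payloads (per-article metadata restricted to one ID; per-article figure
lists) serialize as key-sorted JSON, so identical inputs give
byte-identical files. Annotated article XML wraps mention spans in
`<mention pdb="…">` and term spans in `<term ontology="…" term="…">`;
stripping annotation elements recovers every unit text byte-identically.
Overlaps are resolved by precedence — a PDB mention beats a term, which
is dropped and logged; identical term spans from different ontologies
nest; partially overlapping terms keep the first in (start, end,
ontology, term) order. Payloads are files, not HTTP responses: transport
and caching are deployment concerns, not method.

## The synthetic corpus

The generator emulates exactly the discriminations the miner must make.
Each article contains, in dedicated units: planted lexicon IDs in plain
prose; blacklisted IDs beside a cue term (must survive); blacklisted IDs
with no cue (must be filtered); year tokens; and pattern-conformant
tokens absent from the lexicon. Ground truth is exact by construction —
the filler vocabulary is purely alphabetic (a candidate must start with
a digit), contains no cue-term substrings, and is disjoint from the
ontology-term vocabulary; each planted payload gets its own text unit so
a cue can never leak into a decoy's unit. Offsets are computed on the
already-normalized unit text, so they survive parsing unchanged, which
the tests assert directly.

Default corpus conditions: 100 articles; 2–4 planted IDs per article
(~20 % planted twice in one unit, exercising mention counts > 1); 0–1
each of year decoys, non-lexicon decoys, cue-less blacklist decoys and
cue-bearing blacklist plants per article; ~25 % of ID plants land in
figure captions. That yields roughly 300–400 recoverable mentions and
150 decoys per corpus, enough that a systematic filter error cannot hide
in sampling noise while a 50-corpus sweep still runs in seconds.

Synthetic ontologies plant nested multi-word names (some names extend
another by one token) to exercise longest-match; synthetic chain sets
descend from one random ancestor by independent per-site point mutation
(default rate 0.1, length 200), so each chain's true mutation count is
recorded and identity to the ancestor is predictable — gapless descent
makes expected identity 100 × (1 − rate), with the alignment free only
to raise it via compensating gaps.

What the generator does *not* emulate: realistic English (filler is a
bag-of-words), PMC's full DTD surface, citation-network structure, or
ambiguity that genuinely requires semantic disambiguation. Passing the
planted-recovery tests therefore shows the mechanics — pattern,
validation, filtering, offsets, aggregation, export — are exact; it
does not certify precision/recall on real prose, where the cue list and
blacklist are curation inputs.

## Numerical and design choices

* Degenerate inputs: empty text yields no candidates; an empty lexicon
  is a configuration error (silently mining nothing would look like a
  clean run); an unknown PDB ID queried against the table is an empty
  result, not an error, mirroring a valid-but-unmentioned structure.
* Determinism: every generator is a pure function of its seed; two runs
  of the pipeline on the same inputs produce byte-identical exports.
* Problem sizes in the shipped verification (50 × 100-article corpora,
  1,000 oracle texts against a 500-term dictionary, 500 exhaustively
  enumerated alignment pairs of length ≤ 6, one 200-article invariant
  corpus) were chosen so each check covers thousands of decisions yet
  the whole sweep completes in well under a minute on one CPU.
* Known limitations: no chain- or ligand-level sub-identifiers; no
  machine-learned disambiguation; table and reference-list text is never
  mined; corpus-scale statistics depend entirely on the corpus supplied.
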