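"""Structure–article association tables, co-occurrence and sequence identity.

Mined mentions aggregate into a bipartite table (PDB ID × article).  From
it we derive the two literature views the pipeline exists for: the ranking
of structures by how many distinct articles mention them, and, for a
target structure, the other structures co-occurring in the same articles.
Co-occurring pairs are annotated with percent sequence identity from a
global (Needleman–Wunsch) alignment; for multi-chain entries the
best-scoring chain pair is reported.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .mining import Mention

__all__ = [
    "AssociationTable",
    "CooccurrencePair",
    "ChainSet",
    "build_associations",
    "cooccurring_ids",
    "rank_by_article_count",
    "sequence_identity",
    "global_align",
    "best_chain_similarity",
    "read_chain_fasta",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_FASTA_HEADER_RE = re.compile(r"^>(\S+)")


@dataclass
class AssociationTable:
    """Bidirectional map between PDB IDs and the articles mentioning them.

    ``by_id[pdb_id][pmc_id]`` is the mention count of that ID in that
    article (≥ 1); ``by_article`` is the transpose with counts dropped.
    """

    by_id: dict[str, dict[str, int]] = field(default_factory=dict)
    by_article: dict[str, set[str]] = field(default_factory=dict)

    def article_count(self, pdb_id: str) -> int:
        return len(self.by_id.get(pdb_id, ()))


def build_associations(mentions: Iterable[Mention]) -> AssociationTable:
    """Aggregate corpus-wide mentions; exact tally, empty input → empty table."""
    by_id: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    by_article: dict[str, set[str]] = defaultdict(set)
    for m in mentions:
        by_id[m.pdb_id][m.pmc_id] += 1
        by_article[m.pmc_id].add(m.pdb_id)
    return AssociationTable(
        by_id={i: dict(a) for i, a in by_id.items()},
        by_article=dict(by_article),
    )


@dataclass
class CooccurrencePair:
    """Two PDB IDs sharing at least one article (``id_a < id_b``)."""

    id_a: str
    id_b: str
    shared_articles: frozenset[str]
    identity_percent: float | None = None
    best_chain_pair: tuple[str, str] | None = None

    def other(self, pdb_id: str) -> str:
        return self.id_b if pdb_id == self.id_a else self.id_a


def cooccurring_ids(table: AssociationTable, pdb_id: str,
                    chain_sets: Mapping[str, "ChainSet"] | None = None) -> list[CooccurrencePair]:
    """All other IDs found in the same articles as *pdb_id*.

    Sorted by number of shared articles (descending), then lexicographic.
    When chain sequences are available for both members of a pair the
    best-chain identity is attached.  Unknown IDs yield an empty list.
    """
    articles = table.by_id.get(pdb_id)
    if not articles:
        return []
    shared: dict[str, set[str]] = defaultdict(set)
    for pmc_id in articles:
        for other in table.by_article[pmc_id]:
            if other != pdb_id:
                shared[other].add(pmc_id)
    pairs = []
    for other, arts in shared.items():
        a, b = sorted((pdb_id, other))
        pair = CooccurrencePair(id_a=a, id_b=b, shared_articles=frozenset(arts))
        if chain_sets and a in chain_sets and b in chain_sets:
            ident, ca, cb = best_chain_similarity(chain_sets[a], chain_sets[b])
            pair.identity_percent = ident
            pair.best_chain_pair = (ca, cb)
        pairs.append(pair)
    pairs.sort(key=lambda p: (-len(p.shared_articles), p.other(pdb_id)))
    return pairs


def rank_by_article_count(table: AssociationTable, k: int) -> list[tuple[str, int]]:
    """Top-*k* structures by distinct-article count, ties lexicographic.

    Distinct articles — not total mentions — is the count: a structure
    discussed heavily in one paper still ranks below one touched by two.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    ranked = sorted(table.by_id, key=lambda i: (-len(table.by_id[i]), i))
    return [(i, len(table.by_id[i])) for i in ranked[:k]]


# ---------------------------------------------------------------------------
# Pairwise sequence identity
# ---------------------------------------------------------------------------

def _check_sequence(seq: str, which: str) -> str:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{which} sequence has non-amino-acid characters: {sorted(bad)}")
    return seq


def global_align(seq_a: str, seq_b: str) -> tuple[str, str, int]:
    """Needleman–Wunsch global alignment: match +1, mismatch −1, linear
    gap −1.  Traceback ties are broken by preferring diagonal, then up
    (gap in ``seq_b``), then left, which fixes one reported optimal
    alignment.  Returns ``(aligned_a, aligned_b, score)``.
    """
    a = _check_sequence(seq_a, "first")
    b = _check_sequence(seq_b, "second")
    n, m = len(a), len(b)
    # score matrix, (n+1) x (m+1)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if ai == b[j - 1] else -1)
            up = prev[j] - 1
            left = row[j - 1] - 1
            row[j] = max(diag, up, left)
    # traceback from (n, m); tie order: diagonal, up, left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        s = score[i][j]
        if i > 0 and j > 0 and s == score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and s == score[i - 1][j] - 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity = 100 × matching columns ÷ total alignment columns, gap
    columns included in the denominator.  Symmetric; 100.0 iff the
    sequences are equal.
    """
    aln_a, aln_b, _ = global_align(seq_a, seq_b)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return 100.0 * matches / len(aln_a)


@dataclass(frozen=True)
class ChainSet:
    """The polypeptide chains of one PDB entry, one-letter amino-acid codes."""

    pdb_id: str
    chains: Mapping[str, str]

    def __post_init__(self):
        if not self.chains:
            raise ValueError(f"{self.pdb_id}: chain set is empty")
        for chain_id, seq in self.chains.items():
            _check_sequence(seq, f"{self.pdb_id} chain {chain_id}")


def best_chain_similarity(a: ChainSet, b: ChainSet) -> tuple[float, str, str]:
    """Highest percent identity over the chain cross-product of two entries.

    When several chain pairs tie, the lexicographically smallest
    ``(chain_a, chain_b)`` is reported.
    """
    best: tuple[float, str, str] | None = None
    for ca in sorted(a.chains):
        for cb in sorted(b.chains):
            ident = sequence_identity(a.chains[ca], b.chains[cb])
            if best is None or ident > best[0]:
                best = (ident, ca, cb)
    assert best is not None
    return best


def read_chain_fasta(text: str) -> dict[str, ChainSet]:
    """Read chain sequences from FASTA with ``PDBID_CHAIN`` headers.

    Returns one :class:`ChainSet` per PDB entry.
    """
    chains: dict[str, dict[str, str]] = defaultdict(dict)
    current: tuple[str, str] | None = None
    seq_parts: list[str] = []

    def flush():
        if current is not None:
            pdb_id, chain_id = current
            chains[pdb_id][chain_id] = "".join(seq_parts)

    for line in text.splitlines():
        m = _FASTA_HEADER_RE.match(line)
        if m:
            flush()
            header = m.group(1)
            if "_" not in header:
                raise ValueError(f"FASTA header {header!r} is not PDBID_CHAIN")
            pdb_id, chain_id = header.split("_", 1)
            current = (pdb_id.upper(), chain_id)
            seq_parts = []
        elif line.strip():
            seq_parts.append(line.strip())
    flush()
    return {pdb_id: ChainSet(pdb_id, dict(c)) for pdb_id, c in chains.items()}
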