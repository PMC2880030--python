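"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by a method deliberately
different from the implementation: exhaustive scanning/enumeration rather
than regex, sliding windows or dynamic programming.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def candidate_scan(text: str) -> list[tuple[str, int, int]]:
    """Check every length-4 substring against the candidate predicate."""
    out = []
    for i in range(len(text) - 3):
        token = text[i:i + 4]
        before = text[i - 1] if i > 0 else ""
        after = text[i + 4] if i + 4 < len(text) else ""
        if before.isalnum() or after.isalnum():
            continue
        if not token[0].isdigit() or token[0] == "0":
            continue
        rest = token[1:]
        if all(c.isalnum() for c in rest) and any(c.isalpha() for c in rest):
            out.append((token, i, i + 4))
    return out


def longest_match_tagging(text: str, entries: dict[str, tuple[str, str, str]],
                          max_tokens: int) -> list[tuple[str, int, int]]:
    """Enumerate every token-aligned substring up to *max_tokens*, look it
    up, then greedily select longest-leftmost.  Returns (term_id, start,
    end) triples."""
    tokens = list(_TOKEN_RE.finditer(text))
    candidates: dict[int, list[tuple[int, str]]] = {}
    for i in range(len(tokens)):
        for j in range(i, min(i + max_tokens, len(tokens))):
            key = " ".join(t.group().lower() for t in tokens[i:j + 1])
            entry = entries.get(key)
            if entry is not None:
                candidates.setdefault(i, []).append((j, entry[1]))
    selected = []
    cursor = 0
    for i in range(len(tokens)):
        if i < cursor or i not in candidates:
            continue
        j, term_id = max(candidates[i], key=lambda c: c[0])
        selected.append((term_id, tokens[i].start(), tokens[j].end()))
        cursor = j + 1
    return selected


def enumerate_alignments(a: str, b: str):
    """All global alignments of two sequences as (aligned_a, aligned_b,
    score, moves) with moves in {'d','u','l'} (diagonal / gap-in-b /
    gap-in-a), under match +1, mismatch −1, gap −1."""
    results = []

    def rec(i, j, xs, ys, moves, score):
        if i == len(a) and j == len(b):
            results.append(("".join(xs), "".join(ys), score, "".join(moves)))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, xs + [a[i]], ys + [b[j]], moves + ["d"],
                score + (1 if a[i] == b[j] else -1))
        if i < len(a):
            rec(i + 1, j, xs + [a[i]], ys + ["-"], moves + ["u"], score - 1)
        if j < len(b):
            rec(i, j + 1, xs + ["-"], ys + [b[j]], moves + ["l"], score - 1)

    rec(0, 0, [], [], [], 0)
    return results


_MOVE_RANK = {"d": 0, "u": 1, "l": 2}


def optimal_alignment_identity(a: str, b: str) -> tuple[float, int]:
    """Identity of the optimal alignment a backward traceback preferring
    diagonal, then up, then left would report, found by exhaustive
    enumeration: among maximal-score alignments, the one whose reversed
    move sequence is lexicographically smallest under d < u < l.
    Returns (identity_percent, optimal_score)."""
    alns = enumerate_alignments(a, b)
    best_score = max(s for _, _, s, _ in alns)
    optimal = [x for x in alns if x[2] == best_score]
    chosen = min(optimal, key=lambda x: [_MOVE_RANK[m] for m in reversed(x[3])])
    xs, ys, _, _ = chosen
    matches = sum(1 for x, y in zip(xs, ys) if x == y and x != "-")
    return 100.0 * matches / len(xs), best_score


def cooccurrence_pairs(by_article: dict[str, set[str]]) -> dict[tuple[str, str], set[str]]:
    """Brute-force double loop over article ID-sets."""
    pairs: dict[tuple[str, str], set[str]] = {}
    for pmc_id, ids in by_article.items():
        ordered = sorted(ids)
        for x in ordered:
            for y in ordered:
                if x < y:
                    pairs.setdefault((x, y), set()).add(pmc_id)
    return pairs
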