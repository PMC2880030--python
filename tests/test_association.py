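"""Association tables, co-occurrence, ranking and sequence identity."""

import random

import pytest

from pdblit import (
    ChainSet,
    Mention,
    best_chain_similarity,
    build_associations,
    cooccurring_ids,
    rank_by_article_count,
    read_chain_fasta,
    sequence_identity,
)
from pdblit.association import global_align
from pdblit.synthetic import generate_chain_fasta

from .oracles import cooccurrence_pairs, optimal_alignment_identity


def _mention(pdb_id, pmc_id):
    return Mention(pdb_id, pmc_id, "p-1", "body_para", 0, 4)


def _random_table(rng, n_articles=200, id_pool=40):
    ids = [f"1A{i:02d}" for i in range(id_pool)]
    mentions = []
    for a in range(n_articles):
        pmc = str(a)
        for pdb_id in rng.sample(ids, rng.randint(0, 5)):
            for _ in range(rng.randint(1, 3)):
                mentions.append(_mention(pdb_id, pmc))
    return build_associations(mentions)


class TestBuildAssociations:
    def test_counts_per_article(self):
        ms = [_mention("1HIV", "A")] * 3 + [_mention("1HIV", "B")]
        t = build_associations(ms)
        assert t.by_id == {"1HIV": {"A": 3, "B": 1}}
        assert t.by_article == {"A": {"1HIV"}, "B": {"1HIV"}}

    def test_empty_input(self):
        t = build_associations([])
        assert t.by_id == {} and t.by_article == {}

    def test_transpose_and_conservation_invariants(self):
        t = _random_table(random.Random(5))
        # transpose: exact same (id, article) pair set seen from both sides
        pairs_a = {(i, p) for i, arts in t.by_id.items() for p in arts}
        pairs_b = {(i, p) for p, ids in t.by_article.items() for i in ids}
        assert pairs_a == pairs_b
        assert sum(len(a) for a in t.by_id.values()) == \
            sum(len(i) for i in t.by_article.values())
        assert all(c >= 1 for arts in t.by_id.values() for c in arts.values())

    def test_fixture_manifest_aggregation(self, small_corpus, parsed_articles, lexicon):
        from pdblit import mine_article
        _, manifest = small_corpus
        mentions = []
        for truth in manifest.articles:
            mentions.extend(mine_article(parsed_articles[truth.pmc_id], lexicon))
        t = build_associations(mentions)
        assert t.by_id == manifest.expected_associations()


class TestCooccurrence:
    def test_simple_enumeration(self):
        t = build_associations([_mention("1AAX", "A"), _mention("1AAY", "A"),
                                _mention("1AAX", "B")])
        pairs = cooccurring_ids(t, "1AAX")
        assert len(pairs) == 1
        assert pairs[0].id_a == "1AAX" and pairs[0].id_b == "1AAY"
        assert pairs[0].shared_articles == {"A"}

    def test_singleton_article_has_no_pairs(self):
        t = build_associations([_mention("1AAX", "A")])
        assert cooccurring_ids(t, "1AAX") == []

    def test_unknown_id_empty(self):
        assert cooccurring_ids(build_associations([]), "9XYZ") == []

    def test_matches_brute_force_double_loop(self):
        t = _random_table(random.Random(9), n_articles=200)
        expected = cooccurrence_pairs(t.by_article)
        for pdb_id in t.by_id:
            for pair in cooccurring_ids(t, pdb_id):
                assert pair.shared_articles == expected[(pair.id_a, pair.id_b)]
            n_expected = sum(1 for k in expected if pdb_id in k)
            assert len(cooccurring_ids(t, pdb_id)) == n_expected

    def test_symmetry(self):
        t = _random_table(random.Random(10), n_articles=60)
        for x in t.by_id:
            forward = {(p.id_a, p.id_b): p.shared_articles
                       for p in cooccurring_ids(t, x)}
            for (a, b), shared in forward.items():
                y = b if x == a else a
                back = {(p.id_a, p.id_b): p.shared_articles
                        for p in cooccurring_ids(t, y)}
                assert back[(a, b)] == shared

    def test_sorted_by_shared_count_then_id(self):
        ms = []
        for pmc, ids in [("A", "XY"), ("B", "XY"), ("C", "XZ"), ("D", "XW")]:
            for c in ids:
                ms.append(_mention(f"1AA{c}", pmc))
        t = build_associations(ms)
        pairs = cooccurring_ids(t, "1AAX")
        assert [p.other("1AAX") for p in pairs] == ["1AAY", "1AAW", "1AAZ"]


class TestRanking:
    def test_top_k_distinct_articles_ties_lexicographic(self):
        ms = ([_mention("1BBB", a) for a in "ABC"]
              + [_mention("1AAA", a) for a in "AB"]
              + [_mention("1CCC", a) for a in "XY"]
              + [_mention("1DDD", "A")] * 5)  # many mentions, one article
        ranked = rank_by_article_count(build_associations(ms), 3)
        assert ranked == [("1BBB", 3), ("1AAA", 2), ("1CCC", 2)]

    def test_empty_table(self):
        assert rank_by_article_count(build_associations([]), 5) == []

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rank_by_article_count(build_associations([]), 0)


class TestSequenceIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACDE", "ACDE", 100.0),
        ("AAAA", "CCCC", 0.0),
        ("ACDE", "ACE", 75.0),  # frozen from the exhaustive enumeration oracle
    ])
    def test_frozen_examples(self, a, b, expected):
        assert sequence_identity(a, b) == pytest.approx(expected)
        ident, score = optimal_alignment_identity(a, b)
        assert ident == pytest.approx(expected)
        assert global_align(a, b)[2] == score

    def test_symmetry_and_self_identity(self):
        rng = random.Random(2)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(1, 12)))
            assert sequence_identity(a, b) == pytest.approx(sequence_identity(b, a))
            assert sequence_identity(a, a) == 100.0
            if a != b:
                # 100% requires equality under this scoring
                assert (sequence_identity(a, b) == 100.0) == (a == b)

    def test_score_agrees_with_biopython_aligner(self):
        """Cross-check the optimal score against an independent aligner."""
        from Bio import Align
        aligner = Align.PairwiseAligner(match_score=1, mismatch_score=-1,
                                        open_gap_score=-1, extend_gap_score=-1,
                                        mode="global")
        rng = random.Random(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(1, 15)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(1, 15)))
            assert global_align(a, b)[2] == aligner.score(a, b)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sequence_identity("", "ACDE")
        with pytest.raises(ValueError):
            sequence_identity("ACDE", "AC1E")


class TestBestChainSimilarity:
    def test_identical_chain_attains_100(self):
        a = ChainSet("1AAA", {"A": "MKVLA"})
        b = ChainSet("1BBB", {"A": "WWWWW", "B": "MKVLA"})
        assert best_chain_similarity(a, b) == (100.0, "A", "B")

    def test_single_chain_reduces_to_sequence_identity(self):
        a = ChainSet("1AAA", {"A": "ACDE"})
        b = ChainSet("1BBB", {"A": "ACE"})
        ident, ca, cb = best_chain_similarity(a, b)
        assert ident == sequence_identity("ACDE", "ACE")
        assert (ca, cb) == ("A", "A")

    def test_matches_brute_force_over_cross_product(self):
        rng = random.Random(4)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = ChainSet("1AAA", {c: "".join(rng.choice(aas) for _ in range(rng.randint(1, 20)))
                                  for c in "ABC"})
            b = ChainSet("1BBB", {c: "".join(rng.choice(aas) for _ in range(rng.randint(1, 20)))
                                  for c in "ABC"})
            ident, ca, cb = best_chain_similarity(a, b)
            brute = max(sequence_identity(a.chains[x], b.chains[y])
                        for x in "ABC" for y in "ABC")
            assert ident == pytest.approx(brute)
            assert sequence_identity(a.chains[ca], b.chains[cb]) == pytest.approx(brute)

    def test_empty_chain_set_rejected(self):
        with pytest.raises(ValueError):
            ChainSet("1AAA", {})


class TestChainFasta:
    def test_round_trip_via_generator(self):
        fasta, manifest = generate_chain_fasta(4, chains_per_entry=2, seed=6, length=50)
        sets = read_chain_fasta(fasta)
        assert len(sets) == 4
        for key, info in manifest["chains"].items():
            pdb_id, chain = key.split("_")
            assert sets[pdb_id].chains[chain] == info["sequence"]

    def test_bad_header_rejected(self):
        with pytest.raises(ValueError):
            read_chain_fasta(">NOUNDERSCORE\nACDE\n")
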