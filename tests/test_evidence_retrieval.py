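"""Sentence segmentation, BM25 ranking against a brute-force oracle,
reranking, baselines, and query construction."""

import math
import random
from collections import Counter

import pytest

from citecheck.corpus_model import FineLabel
from citecheck.evidence_retrieval import (
    RetrievalConfig,
    SentenceIndex,
    bm25_rank,
    build_query,
    idf_overlap_scorer,
    rerank,
    title_abstract_evidence,
)
from citecheck.synthetic_fixtures import GeneratorConfig, generate_corpus
from citecheck.textutils import segment_sentences, tokenize

from conftest import make_doc, random_doc


# ---------------------------------------------------------------------------
# Independent brute-force Okapi BM25 (test oracle; shares only the tokenizer)
# ---------------------------------------------------------------------------


def bm25_oracle(query: str, sentences: list[str], k1: float, b: float) -> list[float]:
    docs = [tokenize(s) for s in sentences]
    n = len(docs)
    avgdl = sum(len(d) for d in docs) / n
    q_terms = tokenize(query)
    scores = []
    for d in docs:
        tf = Counter(d)
        score = 0.0
        for t in q_terms:
            df = sum(1 for other in docs if t in other)
            idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
            f = tf[t]
            if f:
                score += idf * f * (k1 + 1.0) / (
                    f + k1 * (1.0 - b + b * len(d) / avgdl)
                )
        scores.append(score)
    return scores


class TestSegmentation:
    def test_two_plain_sentences(self):
        assert [s.text for s in segment_sentences("A fact. Another fact.")] == [
            "A fact.",
            "Another fact.",
        ]

    def test_abbreviations_do_not_split(self):
        out = segment_sentences("Smith et al. (2020) showed X. It held.")
        assert [s.text for s in out] == ["Smith et al. (2020) showed X.", "It held."]

    def test_empty_string(self):
        assert segment_sentences("") == []

    def test_offsets_cover_non_whitespace(self):
        text = "One thing here.  Two things there. Three more!"
        sents = segment_sentences(text)
        covered = "".join(text[s.start : s.end] for s in sents)
        assert covered.replace(" ", "") == text.replace(" ", "")
        starts = [s.start for s in sents]
        assert starts == sorted(starts)
        for s in sents:
            assert text[s.start : s.end] == s.text


class TestBm25:
    def test_exact_sentence_match_ranks_first(self):
        doc = make_doc(
            [
                "Kinase alpha promotes fibrosis.",
                "Unrelated beta talks about plasma.",
                "Different gamma covers serum markers.",
            ]
        )
        ranked = bm25_rank("kinase alpha promotes fibrosis", doc)
        assert ranked.ranking[0][0] == "doc1:s0000"
        assert ranked.ranking[0][1] > ranked.ranking[1][1]

    def test_three_sentence_doc_matches_hand_formula(self):
        sentences = [
            "Insulin lowers glucose.",
            "Insulin insulin signaling cascade expands rapidly.",
            "Cortisol raises glucose strongly.",
        ]
        doc = make_doc(sentences)
        config = RetrievalConfig(first_stage_n=3, top_k=3)
        ranked = bm25_rank("insulin glucose", doc, config)
        expected = bm25_oracle("insulin glucose", sentences, 1.2, 0.75)
        got = dict(ranked.ranking)
        for i, sid in enumerate(f"doc1:s{j:04d}" for j in range(3)):
            assert got[sid] == pytest.approx(expected[i], abs=1e-12)

    def test_oracle_equivalence_on_random_documents(self):
        """Scores match an independent brute-force BM25 on 100 random
        fixture documents of at most 50 sentences, to 1e-9."""
        rng = random.Random(20)
        for trial in range(100):
            n = rng.randint(3, 50)
            doc = random_doc(rng, n, f"d{trial}")
            sentences = [doc.sentences[sid].text for sid in doc.ordered_sentence_ids()]
            query = " ".join(
                rng.choice(tokenize(rng.choice(sentences))) for _ in range(rng.randint(1, 6))
            )
            config = RetrievalConfig(first_stage_n=60, top_k=20)
            ranked = bm25_rank(query, doc, config)
            expected = bm25_oracle(query, sentences, config.bm25_k1, config.bm25_b)
            got = dict(ranked.ranking)
            for i, sid in enumerate(doc.ordered_sentence_ids()):
                if sid in got:
                    assert got[sid] == pytest.approx(expected[i], abs=1e-9)
            # the ranking keeps the top-n by score
            kept = sorted(got.values(), reverse=True)
            dropped = sorted(
                (expected[i] for i, sid in enumerate(doc.ordered_sentence_ids())
                 if sid not in got),
                reverse=True,
            )
            if kept and dropped:
                assert kept[-1] >= dropped[0] - 1e-9

    def test_duplicate_sentences_tie_broken_by_position(self):
        doc = make_doc(
            ["Alpha beta gamma.", "Alpha beta gamma.", "Delta epsilon zeta."]
        )
        ranked = bm25_rank("alpha beta", doc)
        assert ranked.ranking[0][0] == "doc1:s0000"
        assert ranked.ranking[1][0] == "doc1:s0001"
        assert ranked.ranking[0][1] == ranked.ranking[1][1]

    def test_oov_query_flagged_document_order(self):
        doc = make_doc(["Alpha beta.", "Gamma delta.", "Epsilon zeta."])
        ranked = bm25_rank("quasar monsoon", doc)
        assert "oov_query" in ranked.flags
        assert [s for s, _ in ranked.ranking] == [f"doc1:s{i:04d}" for i in range(3)]
        assert all(score == 0.0 for _, score in ranked.ranking)

    def test_added_nonmatching_sentence_preserves_score_signs(self):
        """Appending a sentence sharing no query terms (and not changing the
        df profile of query terms) leaves which-sentences-score-positive
        unchanged."""
        base = ["Alpha beta gamma.", "Beta delta.", "Zeta eta."]
        doc1 = make_doc(base, doc_id="a")
        doc2 = make_doc(base + ["Theta iota kappa."], doc_id="b")
        q = "alpha beta"
        r1 = {s.split(":")[1]: v for s, v in bm25_rank(q, doc1).ranking}
        r2 = {s.split(":")[1]: v for s, v in bm25_rank(q, doc2).ranking}
        for key in r1:
            assert (r1[key] > 0) == (r2[key] > 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RetrievalConfig(first_stage_n=10, top_k=20)
        with pytest.raises(ValueError):
            RetrievalConfig(bm25_b=1.5)
        with pytest.raises(ValueError):
            RetrievalConfig(query_mode="nonsense")


class TestRerank:
    @pytest.fixture
    def ranked_setup(self):
        rng = random.Random(5)
        doc = random_doc(rng, 20, "rr")
        ranked = bm25_rank("kinase enzyme pathway receptor", doc,
                           RetrievalConfig(first_stage_n=20, top_k=20))
        return doc, ranked

    def test_identity_scorer_keeps_order(self, ranked_setup):
        doc, ranked = ranked_setup
        scores = dict(ranked.ranking)

        def scorer(q, sent_text):
            sid = next(
                s for s in doc.sentences if doc.sentences[s].text == sent_text
            )
            return scores[sid]

        out = rerank(ranked, "q", doc, scorer)
        assert [s for s, _ in out.ranking] == [s for s, _ in ranked.ranking]
        assert out.stage == "reranked"

    def test_negated_scorer_reverses_strict_order(self):
        doc = make_doc(["Alpha beta.", "Alpha alpha beta.", "Gamma delta."])
        ranked = bm25_rank("alpha beta", doc, RetrievalConfig(first_stage_n=3, top_k=3))
        scores = dict(ranked.ranking)
        assert len(set(scores.values())) == 3  # strict order

        out = rerank(ranked, "q", doc, lambda q, t: -scores[
            next(s for s in doc.sentences if doc.sentences[s].text == t)
        ])
        assert [s for s, _ in out.ranking] == [s for s, _ in ranked.ranking][::-1]

    def test_failed_scorer_falls_back_with_flag(self, ranked_setup):
        doc, ranked = ranked_setup

        def boom(q, t):
            raise RuntimeError("no weights")

        out = rerank(ranked, "q", doc, boom)
        assert out.ranking == ranked.ranking
        assert any("reranker_failed" in f for f in out.flags)

    def test_idf_overlap_scorer_matches_bruteforce(self):
        doc = make_doc(
            [
                "Kinase enzyme pathway signal.",
                "Kinase pathway only.",
                "Totally different words here.",
            ]
        )
        index = SentenceIndex(doc)
        scorer = idf_overlap_scorer(index)
        query = "kinase enzyme pathway"
        q_terms = set(tokenize(query))
        denom = sum(index.idf(t) for t in q_terms)
        for sid in doc.ordered_sentence_ids():
            text = doc.sentences[sid].text
            expected = sum(
                index.idf(t) for t in q_terms & set(tokenize(text))
            ) / denom
            assert scorer(query, text) == pytest.approx(expected)


class TestTitleAbstract:
    def test_title_then_abstract_in_document_order(self, toy_doc):
        out = title_abstract_evidence(toy_doc, "i1")
        assert out.stage == "title_abstract"
        ids = [sid for sid, _ in out.ranking]
        assert ids[0].startswith("doc1:title:")
        assert ids[1:] == toy_doc.abstract_sentence_ids

    def test_missing_abstract_flagged(self):
        doc = make_doc(["Lone body sentence."], n_abstract=0)
        out = title_abstract_evidence(doc)
        assert any("abstract" in f for f in out.flags)
        assert len(out.ranking) == 1


class TestBuildQuery:
    @pytest.fixture
    def instance(self):
        corpus = generate_corpus(GeneratorConfig(n_instances=30, seed=9))
        # pick an instance whose gold context is just the citance
        return next(
            i for i in corpus.instances
            if i.fine_label is FineLabel.ACCURATE and len(i.context_sentence_ids) == 1
        )

    def test_citance_mode_masks_target(self, instance):
        q = build_query(instance, "citance")
        assert "[cit]" in q or "[multi_cit]" in q
        s, e = instance.marker_span
        assert instance.paragraph_text[s:e] not in q

    def test_gold_context_with_intervening_fills_range(self):
        corpus = generate_corpus(GeneratorConfig(n_instances=60, seed=12))
        inst = next(
            i for i in corpus.instances if len(i.context_sentence_ids) >= 2
        )
        sents = segment_sentences(inst.paragraph_text)
        lo, hi = min(inst.context_sentence_ids), max(inst.context_sentence_ids)
        q = build_query(inst, "gold_context_with_intervening")
        q_tokens = set(tokenize(q))
        for i in range(lo, hi + 1):
            # every sentence between the extremes contributes its content
            # tokens (marker reference numbers are masked away)
            core = [t for t in tokenize(sents[i].text) if not t.isdigit()]
            assert all(tok in q_tokens for tok in core)

    def test_gold_mode_without_context_errors(self, instance):
        with pytest.raises(ValueError, match="context"):
            build_query(instance, "gold_context", context_sentence_ids=[])
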