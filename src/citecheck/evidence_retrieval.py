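"""Evidence sentence retrieval from the reference article.

The retrieval collection is the sentence set of the single reference
article being cited (not a cross-article index).  The first stage scores
every sentence with Okapi BM25 — term frequency saturated by ``k1``, length
normalization controlled by ``b``, inverse document frequency computed over
the within-article sentence collection — and keeps the top
``first_stage_n`` (default 60) candidates.  An optional second-stage
cross-scorer reranks those candidates, after which the top ``k`` sentences
(5, 10 or 20) serve as the evidence set.  A title-plus-abstract baseline is
provided for comparison.

BM25 formula used here, for query term t and sentence S::

    idf(t)   = ln(1 + (N - df(t) + 0.5) / (df(t) + 0.5))
    score(S) = sum_t idf(t) * tf(t,S) * (k1 + 1)
               / (tf(t,S) + k1 * (1 - b + b * |S| / avgdl))

with N the number of sentences in the article, df(t) the number of
sentences containing t, |S| the sentence token count and avgdl the mean
sentence length.  The ``+1`` inside the logarithm keeps idf non-negative
for very common terms.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .annotation_io import mask_markers
from .corpus_model import CitationInstance, ReferenceDocument
from .textutils import SegmentedSentence, segment_sentences, tokenize

__all__ = [
    "RetrievalConfig",
    "RankedEvidence",
    "segment_sentences",
    "SentenceIndex",
    "bm25_rank",
    "rerank",
    "idf_overlap_scorer",
    "RERANKERS",
    "title_abstract_evidence",
    "build_query",
    "QUERY_MODES",
]

QUERY_MODES = ("citance", "gold_context", "gold_context_with_intervening", "title_abstract")


@dataclass(frozen=True)
class RetrievalConfig:
    """Knobs of the retrieval stage.

    ``first_stage_n`` is the BM25 candidate pool size; ``top_k`` the final
    evidence set size.  ``reranker`` names a registered cross-scorer or is
    None for plain BM25 ordering.
    """

    first_stage_n: int = 60
    top_k: int = 20
    query_mode: str = "citance"
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    reranker: str | None = None

    def __post_init__(self) -> None:
        if self.top_k > self.first_stage_n:
            raise ValueError("top_k must not exceed first_stage_n")
        if self.query_mode not in QUERY_MODES:
            raise ValueError(f"unknown query_mode {self.query_mode!r}")
        if self.bm25_k1 <= 0:
            raise ValueError("bm25_k1 must be positive")
        if not 0.0 <= self.bm25_b <= 1.0:
            raise ValueError("bm25_b must be in [0, 1]")


@dataclass
class RankedEvidence:
    """Ordered candidate evidence sentences with scores.

    Scores are non-increasing; ties are broken by document position
    (earlier sentence first).
    """

    instance_id: str
    ranking: list[tuple[str, float]]  # (sentence_id, score)
    stage: str  # "bm25" | "reranked" | "title_abstract"
    flags: list[str] = field(default_factory=list)

    def sentence_ids(self, k: int | None = None) -> list[str]:
        ids = [sid for sid, _ in self.ranking]
        return ids if k is None else ids[:k]


class SentenceIndex:
    """Per-article BM25 statistics over its sentence collection."""

    def __init__(self, doc: ReferenceDocument):
        self.doc = doc
        self.sentence_ids = doc.ordered_sentence_ids()
        self.position = {sid: i for i, sid in enumerate(self.sentence_ids)}
        self.tokens: dict[str, list[str]] = {
            sid: tokenize(doc.sentences[sid].text) for sid in self.sentence_ids
        }
        self.n = len(self.sentence_ids)
        df: Counter[str] = Counter()
        for toks in self.tokens.values():
            df.update(set(toks))
        self.df = df
        total_len = sum(len(t) for t in self.tokens.values())
        self.avgdl = total_len / self.n if self.n else 0.0

    def idf(self, term: str) -> float:
        df = self.df.get(term, 0)
        return math.log(1.0 + (self.n - df + 0.5) / (df + 0.5))

    def score(self, query_terms: Sequence[str], sentence_id: str, k1: float, b: float) -> float:
        toks = self.tokens[sentence_id]
        if not toks:
            return 0.0
        tf = Counter(toks)
        dl = len(toks)
        norm = k1 * (1.0 - b + b * dl / self.avgdl) if self.avgdl else k1
        total = 0.0
        for term in query_terms:
            f = tf.get(term, 0)
            if f:
                total += self.idf(term) * f * (k1 + 1.0) / (f + norm)
        return total


def bm25_rank(
    query: str,
    doc: ReferenceDocument,
    config: RetrievalConfig = RetrievalConfig(),
    instance_id: str = "",
    index: SentenceIndex | None = None,
) -> RankedEvidence:
    """Score every article sentence against ``query`` with Okapi BM25 and
    return the top ``first_stage_n`` in score order.

    A query with no in-vocabulary term yields all-zero scores, a
    document-order ranking and an ``oov_query`` flag.  A pre-built
    :class:`SentenceIndex` may be passed to amortize indexing across
    queries against the same article.
    """
    idx = index if index is not None else SentenceIndex(doc)
    if idx.n == 0:
        raise ValueError(f"document {doc.doc_id} has no sentences")
    terms = tokenize(query)
    if not terms:
        raise ValueError("query tokenizes to no terms")
    flags: list[str] = []
    if not any(t in idx.df for t in terms):
        flags.append("oov_query")
    scored = [
        (sid, idx.score(terms, sid, config.bm25_k1, config.bm25_b))
        for sid in idx.sentence_ids
    ]
    scored.sort(key=lambda item: (-item[1], idx.position[item[0]]))
    return RankedEvidence(instance_id, scored[: config.first_stage_n], "bm25", flags)


CrossScorer = Callable[[str, str], float]


def rerank(
    candidates: RankedEvidence,
    query: str,
    doc: ReferenceDocument,
    scorer: CrossScorer,
) -> RankedEvidence:
    """Reorder a candidate list with a query-sentence cross-scorer.

    The sentence set is unchanged; ties break by document position.  If the
    scorer raises, the input ordering is returned with a flag rather than
    failing the stage.
    """
    position = {sid: i for i, sid in enumerate(doc.ordered_sentence_ids())}
    try:
        rescored = [
            (sid, float(scorer(query, doc.sentences[sid].text)))
            for sid, _ in candidates.ranking
        ]
    except Exception:  # noqa: BLE001 - degraded-mode fallback per contract
        return replace(
            candidates, flags=candidates.flags + ["reranker_failed: kept bm25 order"]
        )
    rescored.sort(key=lambda item: (-item[1], position[item[0]]))
    return RankedEvidence(candidates.instance_id, rescored, "reranked", list(candidates.flags))


def idf_overlap_scorer(index: SentenceIndex) -> CrossScorer:
    """IDF-weighted token-overlap cross-scorer (the default desk-scale
    reranker; a neural cross-encoder can be plugged in through the same
    contract).

    score(q, s) = sum of idf over shared terms / sum of idf over query terms.
    """

    def score(query: str, sentence: str) -> float:
        q = set(tokenize(query))
        s = set(tokenize(sentence))
        if not q:
            return 0.0
        denom = sum(index.idf(t) for t in q)
        if denom == 0.0:
            return 0.0
        return sum(index.idf(t) for t in q & s) / denom

    return score


#: Registry of named rerankers: name -> factory(SentenceIndex) -> scorer.
RERANKERS: dict[str, Callable[[SentenceIndex], CrossScorer]] = {
    "idf_overlap": idf_overlap_scorer,
}


def title_abstract_evidence(
    doc: ReferenceDocument, instance_id: str = ""
) -> RankedEvidence:
    """Baseline evidence set: title sentence(s) then abstract sentences in
    document order, with uniform scores."""
    units: list[tuple[str, float]] = []
    title_sents = segment_sentences(doc.title)
    for i, _sent in enumerate(title_sents):
        units.append((f"{doc.doc_id}:title:{i}", 1.0))
    flags: list[str] = []
    if doc.abstract_sentence_ids:
        units.extend((sid, 1.0) for sid in doc.abstract_sentence_ids)
    else:
        flags.append("no_abstract")
    return RankedEvidence(instance_id, units, "title_abstract", flags)


def build_query(
    instance: CitationInstance,
    mode: str = "citance",
    context_sentence_ids: Sequence[int] | None = None,
) -> str:
    """Build the retrieval query from the citing paragraph.

    Modes: ``citance`` (masked citance only), ``gold_context`` (the
    annotated context sentences), ``gold_context_with_intervening`` (the
    context sentences plus any sentences lying between them).  Sentences
    are concatenated in paragraph order with citation markers masked.
    ``context_sentence_ids`` overrides the instance's gold context (e.g.
    to query with predicted context).
    """
    if mode not in ("citance", "gold_context", "gold_context_with_intervening"):
        raise ValueError(f"build_query does not handle mode {mode!r}")
    sents = segment_sentences(instance.paragraph_text)
    citance_idx = instance.citance_index()
    if mode == "citance":
        chosen = [citance_idx]
    else:
        ids = context_sentence_ids
        if ids is None:
            ids = instance.context_sentence_ids
        if not ids:
            raise ValueError(
                f"mode {mode!r} requires context sentences (instance "
                f"{instance.instance_id!r})"
            )
        chosen = sorted(set(ids))
        if mode == "gold_context_with_intervening":
            chosen = list(range(min(chosen), max(chosen) + 1))
    parts: list[str] = []
    for i in chosen:
        sent = sents[i]
        parts.append(_mask_in_sentence(sent, instance))
    return " ".join(parts)


def _mask_in_sentence(sent: SegmentedSentence, instance: CitationInstance) -> str:
    target = None
    ts, te = instance.marker_span
    if sent.start <= ts < sent.end:
        target = (ts - sent.start, min(te, sent.end) - sent.start)
    others = [
        (s - sent.start, min(e, sent.end) - sent.start)
        for s, e in instance.other_marker_spans
        if sent.start <= s < sent.end
    ]
    return mask_markers(sent.text, target, others)
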