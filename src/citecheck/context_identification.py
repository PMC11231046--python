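"""Citation context identification.

Given the citing paragraph and the target citation marker, decide which
sentences of the paragraph discuss the cited reference.  The *citance* (the
sentence containing the marker) is always part of the context, which makes
the citance-only baseline's precision structurally perfect against any gold
standard that itself contains the citance.  Richer methods classify each
remaining sentence as context or not via a pluggable sentence-pair scorer
applied to marker-masked text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .annotation_io import locate_markers, mask_markers
from .corpus_model import Span
from .textutils import SegmentedSentence, sentence_index_at, tokenize

__all__ = [
    "ContextPrediction",
    "citance_baseline",
    "classify_context",
    "jaccard_scorer",
    "CONTEXT_SCORERS",
]

#: Sentence-pair scorer contract: (masked sentence, masked citance) -> [0, 1].
PairScorer = Callable[[str, str], float]


@dataclass
class ContextPrediction:
    instance_id: str
    sentence_ids: list[int]  # paragraph-local, unique, ordered
    method: str
    flags: list[str] = field(default_factory=list)


def _citance_index(
    sentences: Sequence[SegmentedSentence], marker_span: Span
) -> tuple[int, list[str]]:
    flags: list[str] = []
    idx = sentence_index_at(list(sentences), marker_span[0])
    if marker_span[1] > sentences[idx].end:
        # marker straddles a (mis-)detected sentence boundary
        flags.append("marker crosses sentence boundary; assigned to start sentence")
    return idx, flags


def citance_baseline(
    sentences: Sequence[SegmentedSentence],
    marker_span: Span,
    instance_id: str = "",
) -> ContextPrediction:
    """Context = the citance only.

    Predicting exactly the sentence containing the marker gives a context
    set that is a subset of any gold context (the citance is in the gold by
    definition), hence precision 1.0 by construction.
    """
    if not sentences:
        raise ValueError("empty paragraph")
    idx, flags = _citance_index(sentences, marker_span)
    return ContextPrediction(instance_id, [idx], "citance_baseline", flags)


def jaccard_scorer(sentence: str, citance: str) -> float:
    """Token Jaccard similarity between masked sentence and masked citance."""
    a, b = set(tokenize(sentence)), set(tokenize(citance))
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


#: Registry of named context scorers for pipeline configuration.
CONTEXT_SCORERS: dict[str, PairScorer] = {"jaccard": jaccard_scorer}


def _masked(sent: SegmentedSentence, target: Span | None, others: Sequence[Span]) -> str:
    """Mask markers inside one sentence, offsets translated to local frame."""
    local_target = None
    if target is not None and sent.start <= target[0] < sent.end:
        local_target = (target[0] - sent.start, min(target[1], sent.end) - sent.start)
    local_others = [
        (s - sent.start, min(e, sent.end) - sent.start)
        for s, e in others
        if sent.start <= s < sent.end
    ]
    if local_target is None and not local_others:
        # fall back to the default dialect inventory for unannotated markers
        found = locate_markers(sent.text)
        local_others = [m.span for m in found]
    return mask_markers(sent.text, local_target, local_others)


def classify_context(
    sentences: Sequence[SegmentedSentence],
    marker_span: Span,
    backend: PairScorer,
    threshold: float = 0.5,
    other_marker_spans: Sequence[Span] = (),
    instance_id: str = "",
) -> ContextPrediction:
    """Score every paragraph sentence against the citance; keep those at or
    above ``threshold``, plus the citance itself (always included).

    Markers are masked (``[cit]`` / ``[multi_cit]`` / ``[other_cit]``)
    before scoring so the scorer sees citation structure, not reference
    numbers.  Backend failures propagate annotated with the instance id.
    """
    if not sentences:
        raise ValueError("empty paragraph")
    idx, flags = _citance_index(sentences, marker_span)
    masked_citance = _masked(sentences[idx], marker_span, other_marker_spans)
    keep = {idx}
    for sent in sentences:
        if sent.index == idx:
            continue
        masked_sent = _masked(sent, None, other_marker_spans)
        try:
            score = backend(masked_sent, masked_citance)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"context backend failed on instance {instance_id!r}, "
                f"sentence {sent.index}: {exc}"
            ) from exc
        if score >= threshold:
            keep.add(sent.index)
    return ContextPrediction(instance_id, sorted(keep), "classifier", flags)
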