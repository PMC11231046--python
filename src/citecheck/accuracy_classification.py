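"""Three-way citation accuracy classification.

The citation context acts as a claim and the retrieved evidence sentences
as its evidence source; a backend assigns ACCURATE / NOT_ACCURATE /
IRRELEVANT, echoing the Support / Refute / Not-Enough-Information scheme of
claim verification.  Backends are pluggable: a transparent lexical rule
cascade (the default at desk scale), a gold-reading oracle for plumbing
checks, a trainable lexical-feature logistic-regression backend produced by
:func:`finetune_harness`, and an in-context-learning path that renders a
prompt for a generative model and parses its reply (no live API calls are
made here).

Heuristic rule cascade, driven by the IDF-weighted token overlap between
the masked context and each evidence sentence (directional: shared weight
over context weight):

1. no evidence, or best overlap < ``low``  -> IRRELEVANT
2. best overlap >= ``high`` and a negation-polarity or numeric mismatch
   against the best sentence                -> NOT_ACCURATE
3. best overlap >= ``high`` otherwise      -> ACCURATE
4. intermediate overlap                    -> NOT_ACCURATE (related but not
   fully substantiating)

The thresholds (low=0.1, high=0.6) are package choices documented in
``docs/methods.md``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Protocol, Sequence

from .corpus_model import CitationInstance, CoarseLabel, consolidate_label
from .textutils import extract_numbers, tokenize

__all__ = [
    "AccuracyPrediction",
    "BackendContractError",
    "OptionalBackendUnavailable",
    "classify",
    "HeuristicVerifier",
    "heuristic_backend",
    "make_oracle_backend",
    "finetune_harness",
    "Demonstration",
    "PromptBundle",
    "build_icl_prompt",
    "parse_icl_response",
    "ICL_MAX_EVIDENCE",
]

LABELS = (CoarseLabel.ACCURATE, CoarseLabel.NOT_ACCURATE, CoarseLabel.IRRELEVANT)


class BackendContractError(RuntimeError):
    """A backend emitted an unknown label or malformed scores."""


class OptionalBackendUnavailable(RuntimeError):
    """A requested optional (e.g. neural) backend has no assets installed."""


class Backend(Protocol):
    """Backend contract: scores per coarse label for one instance."""

    def __call__(
        self,
        context: str,
        evidence: Sequence[str],
        instance_id: str = "",
    ) -> Mapping[CoarseLabel, float]: ...


@dataclass
class AccuracyPrediction:
    instance_id: str
    label: CoarseLabel
    score_per_label: dict[CoarseLabel, float]
    backend: str
    rationale: Optional[str] = None

    def __post_init__(self) -> None:
        total = sum(self.score_per_label.values())
        if abs(total - 1.0) > 1e-6:
            raise BackendContractError(f"scores sum to {total}, not 1")
        best = max(self.score_per_label, key=lambda lab: self.score_per_label[lab])
        if best is not self.label:
            raise BackendContractError("label is not the argmax of score_per_label")


def classify(
    context: str,
    evidence: Sequence[str],
    backend: Backend,
    backend_name: str = "backend",
    instance_id: str = "",
) -> AccuracyPrediction:
    """Run a backend on one (context, evidence) pair and validate its output.

    The context is expected marker-masked; the evidence list may be empty
    (typical for IRRELEVANT or ETIQUETTE gold items).
    """
    if not context.strip():
        raise ValueError(f"empty context for instance {instance_id!r}")
    raw = backend(context, evidence, instance_id=instance_id)
    scores: dict[CoarseLabel, float] = {}
    for key, val in raw.items():
        if isinstance(key, str):
            try:
                key = CoarseLabel(key)
            except ValueError as exc:
                raise BackendContractError(f"unknown label {key!r}") from exc
        elif not isinstance(key, CoarseLabel):
            raise BackendContractError(f"unknown label {key!r}")
        scores[key] = float(val)
    for lab in LABELS:
        scores.setdefault(lab, 0.0)
    total = sum(scores.values())
    if total <= 0:
        raise BackendContractError("backend emitted non-positive score mass")
    scores = {lab: v / total for lab, v in scores.items()}
    label = max(LABELS, key=lambda lab: scores[lab])
    return AccuracyPrediction(instance_id, label, scores, backend_name)


# ---------------------------------------------------------------------------
# Heuristic lexical verifier
# ---------------------------------------------------------------------------

_NEGATION_WORDS = frozenset(
    "no not never none neither nor cannot cant wont dont doesnt didnt isnt "
    "arent wasnt werent without fail fails failed lack lacks lacked "
    "absent unable".split()
)
_NT_RE = re.compile(r"n't\b")


def _negation_parity(text: str) -> int:
    toks = tokenize(text, drop_stopwords=False)
    count = sum(1 for t in toks if t in _NEGATION_WORDS)
    count += len(_NT_RE.findall(text.lower()))
    return count % 2


class HeuristicVerifier:
    """Transparent rule-cascade verifier over lexical overlap.

    ``idf`` maps terms to weights (falling back to ``default_idf`` for
    unseen terms); pass the reference article's BM25 index weights so
    topical terms dominate function-like ones.  With no ``idf`` every term
    weighs 1 (plain token overlap).
    """

    name = "heuristic"

    def __init__(
        self,
        low: float = 0.1,
        high: float = 0.6,
        idf: Callable[[str], float] | None = None,
    ):
        if not 0.0 <= low < high <= 1.0:
            raise ValueError("need 0 <= low < high <= 1")
        self.low = low
        self.high = high
        self.idf = idf if idf is not None else (lambda _t: 1.0)

    def overlap(self, context_tokens: set[str], sentence: str) -> float:
        if not context_tokens:
            return 0.0
        sent_tokens = set(tokenize(sentence))
        denom = sum(self.idf(t) for t in context_tokens)
        if denom == 0.0:
            return 0.0
        return sum(self.idf(t) for t in context_tokens & sent_tokens) / denom

    @staticmethod
    def _numeric_mismatch(context: str, best_sentence: str) -> bool:
        c_nums = extract_numbers(context)
        s_nums = extract_numbers(best_sentence)
        if not c_nums or not s_nums:
            return False
        return not set(c_nums) <= set(s_nums)

    def __call__(
        self,
        context: str,
        evidence: Sequence[str],
        instance_id: str = "",
    ) -> dict[CoarseLabel, float]:
        ctx_tokens = set(tokenize(context))
        best_overlap = 0.0
        best_sentence = ""
        for sent in evidence:
            ov = self.overlap(ctx_tokens, sent)
            if ov > best_overlap:
                best_overlap, best_sentence = ov, sent
        if not evidence or best_overlap < self.low:
            label = CoarseLabel.IRRELEVANT
            conf = 1.0 if not evidence else (self.low - best_overlap) / self.low
        elif best_overlap >= self.high:
            mismatch = (
                _negation_parity(context) != _negation_parity(best_sentence)
                or self._numeric_mismatch(context, best_sentence)
            )
            label = CoarseLabel.NOT_ACCURATE if mismatch else CoarseLabel.ACCURATE
            conf = min(1.0, (best_overlap - self.high) / (1.0 - self.high) + 0.5)
        else:
            label = CoarseLabel.NOT_ACCURATE
            # confidence peaks mid-band, shrinks toward either threshold
            span = self.high - self.low
            conf = 1.0 - abs(best_overlap - (self.low + span / 2)) / (span / 2)
        conf = min(1.0, max(0.0, conf))
        winner = (1.0 + 2.0 * conf) / 3.0  # in [1/3, 1]
        rest = (1.0 - winner) / 2.0
        return {lab: (winner if lab is label else rest) for lab in LABELS}


def heuristic_backend(
    context: str, evidence: Sequence[str], instance_id: str = ""
) -> dict[CoarseLabel, float]:
    """Module-level default heuristic backend (unit IDF, default thresholds)."""
    return HeuristicVerifier()(context, evidence, instance_id=instance_id)


def make_oracle_backend(gold: Mapping[str, CoarseLabel]) -> Backend:
    """Backend that reads the gold coarse label by instance id (plumbing
    checks only — it sees no text)."""

    def backend(
        context: str, evidence: Sequence[str], instance_id: str = ""
    ) -> dict[CoarseLabel, float]:
        label = gold[instance_id]
        return {lab: (1.0 if lab is label else 0.0) for lab in LABELS}

    backend.name = "oracle"  # type: ignore[attr-defined]
    return backend


# ---------------------------------------------------------------------------
# Trainable backend harness
# ---------------------------------------------------------------------------


def _pair_features(context: str, evidence: Sequence[str]) -> list[float]:
    verifier = HeuristicVerifier()
    ctx_tokens = set(tokenize(context))
    overlaps = sorted(
        (verifier.overlap(ctx_tokens, sent) for sent in evidence), reverse=True
    )
    best = overlaps[0] if overlaps else 0.0
    mean = sum(overlaps) / len(overlaps) if overlaps else 0.0
    best_sent = ""
    if evidence:
        best_sent = max(evidence, key=lambda s: verifier.overlap(ctx_tokens, s))
    neg = float(_negation_parity(context) != _negation_parity(best_sent))
    num = float(HeuristicVerifier._numeric_mismatch(context, best_sent))
    return [best, mean, neg, num, float(len(evidence)), float(len(ctx_tokens))]


def finetune_harness(
    train_instances: Sequence[CitationInstance],
    model_spec: Mapping[str, object],
    evidence_texts: Mapping[str, Sequence[str]],
    context_texts: Mapping[str, str],
) -> tuple[Backend, dict]:
    """Fit a trainable verification backend and return (backend, manifest).

    The training objective is single-task label classification: the
    rationale-selection loss weight is forced to 0 (evidence sentences are
    taken as given from the retrieval stage, so selecting rationales is not
    learned).  Fine labels are consolidated 8 -> 3 before fitting.

    ``model_spec['model']`` selects the architecture.  The built-in
    ``lexical-logreg`` model is a multinomial logistic regression over
    overlap/polarity/numeric-mismatch features.  Naming a neural model
    whose assets are not installed raises
    :class:`OptionalBackendUnavailable` (never a silent fallback).
    """
    from sklearn.linear_model import LogisticRegression

    model_name = str(model_spec.get("model", "lexical-logreg"))
    if model_name != "lexical-logreg":
        raise OptionalBackendUnavailable(
            f"optional backend unavailable: {model_name!r} has no installed assets"
        )
    if not train_instances:
        raise ValueError("no training instances")
    x: list[list[float]] = []
    y: list[str] = []
    for inst in train_instances:
        ctx = context_texts[inst.instance_id]
        ev = list(evidence_texts.get(inst.instance_id, ()))
        x.append(_pair_features(ctx, ev))
        y.append(consolidate_label(inst.fine_label).value)
    clf = LogisticRegression(max_iter=int(model_spec.get("max_iter", 200)))
    clf.fit(x, y)
    classes = [CoarseLabel(c) for c in clf.classes_]

    def backend(
        context: str, evidence: Sequence[str], instance_id: str = ""
    ) -> dict[CoarseLabel, float]:
        proba = clf.predict_proba([_pair_features(context, list(evidence))])[0]
        scores = {lab: 0.0 for lab in LABELS}
        for lab, p in zip(classes, proba):
            scores[lab] = float(p)
        return scores

    backend.name = model_name  # type: ignore[attr-defined]
    manifest = {
        "model": model_name,
        "loss_weights": {"label": 1.0, "rationale": 0.0},
        "n_train": len(train_instances),
        "label_space": [lab.value for lab in LABELS],
        "consolidation": "fine labels consolidated 8->3 before fitting",
    }
    return backend, manifest


# ---------------------------------------------------------------------------
# In-context learning prompt
# ---------------------------------------------------------------------------

#: Generative-model prompts use only the top-ranked evidence sentences.
ICL_MAX_EVIDENCE = 5

_CLASS_DESCRIPTIONS = {
    "ACCURATE": "The citation context is consistent with the evidence sentences "
    "from the reference article.",
    "NOT_ACCURATE": "The citation context contradicts, overstates, misquotes, or "
    "is otherwise not substantiated by the evidence sentences.",
    "IRRELEVANT": "The reference article contains no information relevant to the "
    "citation context.",
}

_INSTRUCTION = (
    "# Task\n"
    "You are given a citation context from a citing article and evidence "
    "sentences from the article it cites. Decide whether the citation is "
    "ACCURATE, NOT_ACCURATE, or IRRELEVANT.\n\n"
    "# Classes\n"
    + "\n".join(f"- **{k}**: {v}" for k, v in _CLASS_DESCRIPTIONS.items())
)


@dataclass(frozen=True)
class Demonstration:
    context: str
    evidence: tuple[str, ...]
    label: CoarseLabel
    reasoning: str


#: Required demonstration composition: 1 ACCURATE, 2 NOT_ACCURATE, 1 IRRELEVANT.
_DEMO_COMPOSITION = {
    CoarseLabel.ACCURATE: 1,
    CoarseLabel.NOT_ACCURATE: 2,
    CoarseLabel.IRRELEVANT: 1,
}


@dataclass
class PromptBundle:
    instruction: str
    demonstrations: list[Demonstration]
    test_context: str
    test_evidence: list[str]

    def render(self) -> str:
        parts = [self.instruction, ""]
        for i, demo in enumerate(self.demonstrations, start=1):
            parts.append(f"<demonstration id=\"{i}\">")
            parts.append("## Citation context")
            parts.append(demo.context)
            parts.append("## Evidence sentences")
            parts.extend(f"- {s}" for s in demo.evidence)
            parts.append("## Answer")
            parts.append(f"Reasoning: {demo.reasoning}")
            parts.append(f"Label: {demo.label.value}")
            parts.append("</demonstration>")
            parts.append("")
        parts.append("<test>")
        parts.append("## Citation context")
        parts.append(self.test_context)
        parts.append("## Evidence sentences")
        parts.extend(f"- {s}" for s in self.test_evidence)
        parts.append("## Answer")
        parts.append("</test>")
        return "\n".join(parts)


def build_icl_prompt(
    context: str,
    evidence: Sequence[str],
    demos: Sequence[Demonstration],
    max_evidence: int = ICL_MAX_EVIDENCE,
) -> PromptBundle:
    """Assemble the few-shot prompt: instruction with class descriptions,
    four demonstrations (one ACCURATE, two NOT_ACCURATE, one IRRELEVANT, in
    the given order), then the unlabeled test block.  Evidence is truncated
    to ``max_evidence`` top-ranked sentences.
    """
    counts: dict[CoarseLabel, int] = {lab: 0 for lab in LABELS}
    for demo in demos:
        counts[demo.label] += 1
    if counts != _DEMO_COMPOSITION:
        got = {lab.value: n for lab, n in counts.items()}
        raise ValueError(
            "demonstrations must comprise exactly 1 ACCURATE, 2 NOT_ACCURATE "
            f"and 1 IRRELEVANT; got {got}"
        )
    return PromptBundle(
        instruction=_INSTRUCTION,
        demonstrations=list(demos),
        test_context=context,
        test_evidence=list(evidence[:max_evidence]),
    )


_LABEL_RE = re.compile(r"Label:\s*(ACCURATE|NOT_ACCURATE|IRRELEVANT)\b")


def parse_icl_response(reply: str) -> tuple[CoarseLabel, Optional[str]]:
    """Extract (label, reasoning) from a generative-model reply.

    Expects a ``Label: <CLASS>`` line; an optional ``Reasoning: ...`` part
    before it is returned as the rationale.  An unparseable reply raises
    :class:`BackendContractError`.
    """
    m = _LABEL_RE.search(reply)
    if not m:
        raise BackendContractError(f"no parseable label in reply: {reply!r}")
    reasoning = None
    rm = re.search(r"Reasoning:\s*(.+?)(?:\n|Label:)", reply, flags=re.S)
    if rm:
        reasoning = rm.group(1).strip()
    return CoarseLabel(m.group(1)), reasoning
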