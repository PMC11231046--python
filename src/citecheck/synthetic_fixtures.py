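"""Seeded synthetic corpora with planted context, evidence, and labels.

The generator emulates the inputs of the citation-integrity task: citing
paragraphs containing one highlighted target marker (and sometimes other
markers), reference articles of 50-300 sentences organized into titled
sections and paragraphs, and 1-5 planted evidence segments per
evidence-bearing citation.  Fine labels are drawn from the eight-category
taxonomy with a configurable distribution defaulting to the empirical
label distribution of the annotated corpus (60.82% ACCURATE, 18.02% major
errors, 21.16% minor errors).

Each error category is realized by a simple, auditable perturbation of a
planted fact sentence rather than by fluent rewriting:

* ACCURATE — the citance paraphrases a planted evidence sentence (high
  token overlap).
* CONTRADICT — a negation is inserted before the verb.
* MISQUOTE — the quoted number/percentage is altered.
* NOT_SUBSTANTIATE / OVERSIMPLIFY — roughly half of the content words are
  kept and padded with claim words absent from the reference article
  (medium overlap; OVERSIMPLIFY additionally universalizes the claim).
* INDIRECT — the planted evidence sentence itself carries a citation to
  another article, so the reference is not the original source.
* IRRELEVANT — the citance is drawn from a disjoint off-topic vocabulary.
* ETIQUETTE — a multi-citation marker with no clear referent: the citance
  is loosely related to the article (medium overlap) and no evidence
  segment exists.

Generation is a pure function of the configuration (which includes the
seed); regenerating with the same config yields a byte-identical corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import random

from .annotation_io import locate_markers
from .corpus_model import (
    CitationInstance,
    EvidenceSegment,
    FineLabel,
    ReferenceDocument,
    Sentence,
    consolidate_label,
)
from .textutils import extract_numbers, segment_sentences, tokenize

__all__ = [
    "GeneratorConfig",
    "GeneratorConfigError",
    "SyntheticCorpus",
    "generate_corpus",
    "plant_check",
    "TABLE1_DISTRIBUTION",
]


class GeneratorConfigError(ValueError):
    """Infeasible generator configuration."""


#: Empirical fine-label distribution of the annotated corpus (counts over
#: 3063 instances: 1863 / 92 / 243 / 217 / 111 / 38 / 82 / 417).
TABLE1_DISTRIBUTION: dict[FineLabel, float] = {
    FineLabel.ACCURATE: 1863 / 3063,
    FineLabel.CONTRADICT: 92 / 3063,
    FineLabel.NOT_SUBSTANTIATE: 243 / 3063,
    FineLabel.IRRELEVANT: 217 / 3063,
    FineLabel.OVERSIMPLIFY: 111 / 3063,
    FineLabel.MISQUOTE: 38 / 3063,
    FineLabel.INDIRECT: 82 / 3063,
    FineLabel.ETIQUETTE: 417 / 3063,
}

# ---------------------------------------------------------------------------
# Word pools.  Reference articles draw from TOPIC_* pools; claim padding
# draws from GENERIC_WORDS (never used in reference articles, so padded
# words depress lexical overlap); IRRELEVANT citances draw from the
# disjoint OFFTOPIC_* pools.
# ---------------------------------------------------------------------------

TOPIC_NOUNS = (
    "angiogenesis apoptosis autophagy biomarker biofilm chemokine cytokine "
    "dysbiosis endotoxin epithelium fibrosis glycolysis homeostasis hypoxia "
    "inflammation ischemia metabolite methylation microbiome mitochondria "
    "necrosis neurogenesis oxidation pathogenesis permeability phagocytosis "
    "phenotype plasticity polymorphism proliferation proteome remodeling "
    "senescence signaling stenosis thrombosis transcription translocation "
    "vasculature virulence adhesion angiotensin collagen cortisol dopamine "
    "elastase ferritin fibrinogen glucagon glutamate hemoglobin histamine "
    "insulin interferon interleukin keratin lactate leptin lymphocyte "
    "macrophage melatonin microglia myelin neutrophil osteoblast oxytocin "
    "pepsin platelet podocyte protease renin serotonin synapse telomere "
    "thrombin troponin tubulin ubiquitin urease vesicle chemotaxis exosome "
    "fibroblast ganglion genome glycogen hepatocyte hormone integrin keratinocyte "
    "ligand lysosome membrane mucosa myocyte nephron neuron nucleotide organoid "
    "osteocyte pancreas pericyte peroxide plasmid receptor ribosome sarcomere "
    "stroma substrate tendon thalamus toxin transporter villus"
).split()

TOPIC_VERBS = (
    "activates attenuates augments disrupts elevates enhances impairs induces "
    "inhibits mediates modulates potentiates promotes reduces regulates "
    "restores stabilizes stimulates suppresses triggers"
).split()

TOPIC_ADJECTIVES = (
    "acute adaptive chronic cortical endothelial epithelial hepatic hypoxic "
    "inflammatory metabolic microbial mitochondrial neuronal oxidative renal "
    "synaptic systemic transcriptional vascular viral"
).split()

#: Claim/method words absent from generated reference articles.
GENERIC_WORDS = (
    "cohort registry enrollment baseline followup stratification consensus "
    "guideline framework heterogeneity surveillance screening questionnaire "
    "subgroup covariate extrapolation generalizability reproducibility "
    "benchmark paradigm"
).split()

OFFTOPIC_NOUNS = (
    "basalt comet glacier magma meteorite nebula quasar sediment tectonics "
    "aurora archipelago estuary monsoon permafrost stratosphere topography "
    "asteroid caldera isotope lithosphere"
).split()
OFFTOPIC_VERBS = "erodes orbits crystallizes drifts accumulates deposits".split()
OFFTOPIC_ADJECTIVES = "volcanic glacial orbital seismic alluvial stellar".split()

FILLER_OPENERS = (
    "Moreover", "Notably", "In recent years", "Across multiple settings",
    "In this framework", "By comparison",
)

_SECTION_HEADINGS = (
    "Abstract", "Introduction", "Methods", "Results", "Discussion", "Conclusions",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic corpus generation.

    Defaults mirror the annotated corpus where it reports the quantity
    (label distribution; ~1.12 context and ~1.56 evidence sentences per
    evidence-bearing citation) and are otherwise fixed desk-scale choices
    documented in ``docs/methods.md``.
    """

    n_reference_docs: int = 20
    sentences_per_doc: tuple[int, int] = (50, 300)
    n_instances: int = 500
    label_distribution: dict[FineLabel, float] = field(
        default_factory=lambda: dict(TABLE1_DISTRIBUTION)
    )
    #: P(number of evidence segments = 1..5) for evidence-bearing labels.
    evidence_count_weights: tuple[float, ...] = (0.65, 0.20, 0.10, 0.03, 0.02)
    #: P(granularity = sentence / paragraph / section) per segment.
    granularity_weights: tuple[float, float, float] = (0.80, 0.15, 0.05)
    #: P(gold context includes the sentence preceding the citance).
    two_sentence_context_prob: float = 0.12
    #: P(a non-citance paragraph sentence carries another citation marker).
    other_marker_prob: float = 0.20
    #: P(the citance itself carries a second, non-target marker).
    citance_other_marker_prob: float = 0.10
    #: P(a planted fact sentence quotes a number; MISQUOTE facts always do).
    number_prob: float = 0.30
    #: P(a non-ETIQUETTE target marker encloses multiple references).
    multi_marker_prob: float = 0.08
    #: Fraction of fact content words kept for medium-overlap perturbations.
    medium_keep_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference_docs <= 0 or self.n_instances <= 0:
            raise GeneratorConfigError("counts must be positive")
        lo, hi = self.sentences_per_doc
        if not (0 < lo <= hi):
            raise GeneratorConfigError("bad sentences_per_doc range")
        total = sum(self.label_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorConfigError(
                f"label_distribution sums to {total}, expected 1"
            )
        if any(p < 0 for p in self.label_distribution.values()):
            raise GeneratorConfigError("negative label probability")
        if len(self.evidence_count_weights) != 5:
            raise GeneratorConfigError("evidence_count_weights needs 5 entries")


@dataclass
class SyntheticCorpus:
    """Generated reference documents, citation instances, and gold maps."""

    documents: dict[str, ReferenceDocument]
    instances: list[CitationInstance]
    #: instance id -> planted (sentence-level) evidence sentence ids.
    retrieval_gold: dict[str, list[str]]
    config: GeneratorConfig

    def gold_coarse_labels(self) -> dict[str, str]:
        return {i.instance_id: i.coarse_label.value for i in self.instances}


# ---------------------------------------------------------------------------
# Sentence realization
# ---------------------------------------------------------------------------


def _render(words: Sequence[str], marker: str | None = None) -> str:
    body = " ".join(words)
    body = body[0].upper() + body[1:]
    if marker:
        return f"{body} {marker}."
    return f"{body}."


@dataclass
class _Fact:
    """A planted fact: content words plus structural positions used by the
    label-specific perturbations."""

    words: list[str]  # content words, lowercase
    verb_index: int
    number: Optional[str]  # e.g. "45%" or None


class _DocPlan:
    def __init__(self, doc_id: str, n_sentences: int, rng: random.Random):
        self.doc_id = doc_id
        self.n_sentences = n_sentences
        self.nouns = rng.sample(TOPIC_NOUNS, 30)
        self.verbs = rng.sample(TOPIC_VERBS, 10)
        self.adjectives = rng.sample(TOPIC_ADJECTIVES, 8)
        # sentence index -> fixed text (planted evidence), else generated
        self.planted: dict[int, str] = {}
        self.free = list(range(n_sentences))

    def take_slots(self, n: int, rng: random.Random) -> list[int]:
        if len(self.free) < n:
            raise GeneratorConfigError(
                f"document {self.doc_id} too short for requested evidence"
            )
        slots = rng.sample(self.free, n)
        for s in slots:
            self.free.remove(s)
        return slots

    def make_fact(self, rng: random.Random, force_number: bool, number_prob: float) -> _Fact:
        words = [
            rng.choice(self.adjectives),
            rng.choice(self.nouns),
            rng.choice(self.verbs),
            rng.choice(self.nouns),
            "in",
            rng.choice(self.adjectives),
            rng.choice(self.nouns),
        ]
        number = None
        if force_number or rng.random() < number_prob:
            number = f"{rng.randint(5, 95)}%"
            words += ["by", number]
        return _Fact(words=words, verb_index=2, number=number)

    def background_sentence(self, rng: random.Random) -> str:
        fact = self.make_fact(rng, force_number=False, number_prob=0.1)
        return _render(fact.words)


def _generate_document(plan: _DocPlan, rng: random.Random) -> ReferenceDocument:
    texts: list[str] = []
    for i in range(plan.n_sentences):
        texts.append(plan.planted.get(i) or plan.background_sentence(rng))

    # carve sentences into paragraphs (3-6 sentences) and sections
    para_sizes: list[int] = []
    remaining = plan.n_sentences
    while remaining > 0:
        size = min(remaining, rng.randint(3, 6))
        para_sizes.append(size)
        remaining -= size
    abstract_paras = 1 if plan.n_sentences < 80 else 2
    n_body_sections = min(len(_SECTION_HEADINGS) - 1, max(2, len(para_sizes) // 6))
    sections: list[tuple[str, str, list[str]]] = []
    paragraphs: dict[str, list[str]] = {}
    sentences: dict[str, Sentence] = {}

    cursor = 0
    sent_i = 0
    para_i = 0

    def _emit_paragraph(size: int) -> str:
        nonlocal cursor, sent_i, para_i
        pid = f"{plan.doc_id}:p{para_i:03d}"
        para_i += 1
        sids: list[str] = []
        for j in range(size):
            sid = f"{plan.doc_id}:s{sent_i:04d}"
            text = texts[sent_i]
            if j > 0:
                cursor += 1  # single space between sentences
            start = cursor
            cursor += len(text)
            sentences[sid] = Sentence(text, start, cursor)
            sids.append(sid)
            sent_i += 1
        cursor += 2  # paragraph break
        paragraphs[pid] = sids
        return pid

    # abstract first
    abstract_pids = [_emit_paragraph(para_sizes[k]) for k in range(abstract_paras)]
    sections.append((f"{plan.doc_id}:sec0", "Abstract", abstract_pids))
    body_sizes = para_sizes[abstract_paras:]
    per_section = max(1, math.ceil(len(body_sizes) / n_body_sections))
    sec_n = 1
    for start in range(0, len(body_sizes), per_section):
        heading = _SECTION_HEADINGS[min(sec_n, len(_SECTION_HEADINGS) - 1)]
        pids = [_emit_paragraph(sz) for sz in body_sizes[start : start + per_section]]
        sections.append((f"{plan.doc_id}:sec{sec_n}", heading, pids))
        sec_n += 1

    title = _render(
        [rng.choice(plan.nouns), "and", rng.choice(plan.nouns),
         "in", rng.choice(plan.adjectives), rng.choice(plan.nouns)]
    ).rstrip(".")
    abstract_sids = [sid for pid in abstract_pids for sid in paragraphs[pid]]
    doc = ReferenceDocument(
        doc_id=plan.doc_id,
        title=title,
        abstract_sentence_ids=abstract_sids,
        sections=sections,
        paragraphs=paragraphs,
        sentences=sentences,
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Label-specific citance construction
# ---------------------------------------------------------------------------


def _paraphrase(fact: _Fact, rng: random.Random) -> list[str]:
    # copy the fact's content words (stopword-level variation only, plus an
    # occasional appended hedge) so overlap stays firmly in the high band
    words = list(fact.words)
    if rng.random() < 0.5:
        words.insert(0, "as" if rng.random() < 0.5 else "also")
    if rng.random() < 0.35:
        words.append(rng.choice(GENERIC_WORDS))
    return words


def _medium_overlap(
    source_words: Sequence[str], rng: random.Random, keep_frac: float
) -> list[str]:
    content = [w for w in source_words if w not in ("in", "by")]
    n_keep = max(2, round(len(content) * keep_frac))
    kept = content[:n_keep]  # leading words: subject and verb region
    padding = rng.sample(GENERIC_WORDS, min(len(GENERIC_WORDS), max(3, n_keep)))
    return kept + ["across"] + padding


def _citance_words(
    label: FineLabel, fact: Optional[_Fact], plan: _DocPlan, rng: random.Random,
    keep_frac: float, etiquette_source: Sequence[str] = (),
) -> list[str]:
    if label in (FineLabel.ACCURATE, FineLabel.INDIRECT):
        return _paraphrase(fact, rng)
    if label is FineLabel.CONTRADICT:
        words = list(fact.words)
        words.insert(fact.verb_index, "never" if rng.random() < 0.3 else "not")
        return words
    if label is FineLabel.MISQUOTE:
        words = list(fact.words)
        old = fact.number
        old_val = int(old.rstrip("%"))
        new_val = old_val + rng.choice([-1, 1]) * rng.randint(3, 30)
        new_val = min(99, max(1, new_val))
        if new_val == old_val:
            new_val = old_val + 1 if old_val < 99 else old_val - 1
        words[words.index(old)] = f"{new_val}%"
        return words
    if label is FineLabel.NOT_SUBSTANTIATE:
        return _medium_overlap(fact.words, rng, keep_frac)
    if label is FineLabel.OVERSIMPLIFY:
        content = [w for w in fact.words if w not in ("in", "by") and w != fact.number]
        core = [content[1], "always", content[2], content[3]]
        return core + rng.sample(GENERIC_WORDS, 2)
    if label is FineLabel.ETIQUETTE:
        # loosely related to an actual article sentence, so retrieval can
        # surface it but overlap stays in the intermediate band
        return _medium_overlap(list(etiquette_source), rng, keep_frac)
    if label is FineLabel.IRRELEVANT:
        return [
            rng.choice(OFFTOPIC_ADJECTIVES),
            rng.choice(OFFTOPIC_NOUNS),
            rng.choice(OFFTOPIC_VERBS),
            rng.choice(OFFTOPIC_NOUNS),
            "in",
            rng.choice(OFFTOPIC_ADJECTIVES),
            rng.choice(OFFTOPIC_NOUNS),
        ]
    raise AssertionError(label)


def _make_marker(rng: random.Random, multi: bool) -> str:
    if not multi:
        return f"[{rng.randint(1, 40)}]"
    a = rng.randint(1, 30)
    if rng.random() < 0.5:
        return f"[{a}–{a + rng.randint(2, 5)}]"
    return f"[{a},{a + rng.randint(1, 9)}]"


def _filler_sentence(rng: random.Random, marker: str | None = None) -> str:
    opener = rng.choice(FILLER_OPENERS).lower()
    words = [opener, *rng.sample(GENERIC_WORDS, 3)]
    words.append("remains")
    words.append(rng.choice(("debated", "heterogeneous", "understudied")))
    return _render(words, marker)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(config: GeneratorConfig = GeneratorConfig()) -> SyntheticCorpus:
    """Generate (reference documents, citation instances with gold).

    Deterministic: the same configuration (seed included) always yields a
    byte-identical corpus.
    """
    rng = random.Random(config.seed)
    lo, hi = config.sentences_per_doc
    plans = [
        _DocPlan(f"ref{d:03d}", rng.randint(lo, hi), rng)
        for d in range(config.n_reference_docs)
    ]

    labels = list(config.label_distribution)
    weights = [config.label_distribution[lab] for lab in labels]
    instance_labels = rng.choices(labels, weights=weights, k=config.n_instances)

    # plan instances: pick a document with spare slots, plant evidence
    @dataclass
    class _InstancePlan:
        label: FineLabel
        plan: _DocPlan
        fact: Optional[_Fact]
        slots: list[int]

    instance_plans: list[_InstancePlan] = []
    for label in instance_labels:
        candidates = [p for p in plans if len(p.free) >= 5]
        if not candidates:
            raise GeneratorConfigError(
                "documents too short for the requested number of instances"
            )
        plan = rng.choice(candidates)
        fact: Optional[_Fact] = None
        slots: list[int] = []
        if label not in (FineLabel.IRRELEVANT, FineLabel.ETIQUETTE):
            n_seg = rng.choices(
                (1, 2, 3, 4, 5), weights=config.evidence_count_weights
            )[0]
            slots = plan.take_slots(n_seg, rng)
            fact = plan.make_fact(
                rng,
                force_number=label is FineLabel.MISQUOTE,
                number_prob=config.number_prob,
            )
            marker = f"[{rng.randint(41, 99)}]" if label is FineLabel.INDIRECT else None
            plan.planted[slots[0]] = _render(fact.words, marker)
            for extra in slots[1:]:
                plan.planted[extra] = _render(_paraphrase(fact, rng))
        instance_plans.append(_InstancePlan(label, plan, fact, slots))

    documents = {p.doc_id: _generate_document(p, rng) for p in plans}

    instances: list[CitationInstance] = []
    retrieval_gold: dict[str, list[str]] = {}
    for i, iplan in enumerate(instance_plans):
        label, plan = iplan.label, iplan.plan
        doc = documents[plan.doc_id]
        instance_id = f"cit{i:05d}"

        multi = label is FineLabel.ETIQUETTE or rng.random() < config.multi_marker_prob
        marker = _make_marker(rng, multi)
        etiquette_source: list[str] = []
        if label is FineLabel.ETIQUETTE:
            source_sid = rng.choice(doc.ordered_sentence_ids())
            etiquette_source = tokenize(doc.sentences[source_sid].text)
        core = _citance_words(
            label, iplan.fact, plan, rng, config.medium_keep_frac, etiquette_source
        )

        citance_other: str | None = None
        if rng.random() < config.citance_other_marker_prob:
            citance_other = f"[{rng.randint(1, 40)}]"
        body = " ".join(core)
        body = body[0].upper() + body[1:]
        marker_off = len(body) + 1
        citance_other_off = None
        if citance_other:
            # stopword-only connective: the extra marker must not perturb
            # content-token overlap
            citance = f"{body} {marker}, as in {citance_other}."
            citance_other_off = marker_off + len(marker) + len(", as in ")
        else:
            citance = f"{body} {marker}."

        two_ctx = rng.random() < config.two_sentence_context_prob and iplan.fact
        para_sents: list[str] = []
        marker_by_sentence: dict[int, str] = {}  # sentence idx -> other marker

        def _append_filler() -> None:
            if rng.random() < config.other_marker_prob:
                om = f"[{rng.randint(1, 40)}]"
                marker_by_sentence[len(para_sents)] = om
                para_sents.append(_filler_sentence(rng, om))
            else:
                para_sents.append(_filler_sentence(rng))

        if rng.random() < 0.5:
            _append_filler()
        related_idx = None
        if two_ctx:
            related = iplan.fact.words[:4] + rng.sample(GENERIC_WORDS, 2)
            related_idx = len(para_sents)
            para_sents.append(_render(related))
        citance_idx = len(para_sents)
        para_sents.append(citance)
        if rng.random() < 0.4:
            _append_filler()

        paragraph_text = " ".join(para_sents)
        sent_offsets: list[int] = []
        pos = 0
        for s in para_sents:
            sent_offsets.append(pos)
            pos += len(s) + 1
        citance_start = sent_offsets[citance_idx]
        marker_span = (citance_start + marker_off, citance_start + marker_off + len(marker))
        other_spans: list[tuple[int, int]] = []
        if citance_other_off is not None:
            other_spans.append(
                (
                    citance_start + citance_other_off,
                    citance_start + citance_other_off + len(citance_other),
                )
            )
        for j, om in marker_by_sentence.items():
            k = para_sents[j].rindex(om)
            other_spans.append((sent_offsets[j] + k, sent_offsets[j] + k + len(om)))

        context_ids = sorted(
            {citance_idx} | ({related_idx} if related_idx is not None else set())
        )

        # primary (fact-exact) sentence first, paraphrase slots after in order
        ordered_slots = iplan.slots[:1] + sorted(iplan.slots[1:])
        planted_sids = [f"{plan.doc_id}:s{slot:04d}" for slot in ordered_slots]
        segments: list[EvidenceSegment] = []
        seen_units: set[tuple[str, str]] = set()
        for sid in planted_sids:
            gran = rng.choices(
                ("sentence", "paragraph", "section"),
                weights=config.granularity_weights,
            )[0]
            if gran == "sentence":
                unit = sid
            elif gran == "paragraph":
                unit = doc.paragraph_of(sid)
            else:
                unit = doc.section_of(sid)
            if (gran, unit) in seen_units:
                continue
            seen_units.add((gran, unit))
            segments.append(EvidenceSegment(plan.doc_id, gran, unit))

        inst = CitationInstance(
            instance_id=instance_id,
            citing_doc_id=f"citing{i:05d}",
            reference_doc_id=plan.doc_id,
            paragraph_text=paragraph_text,
            marker_span=marker_span,
            marker_multiplicity="multi" if multi else "single",
            other_marker_spans=sorted(other_spans),
            context_sentence_ids=context_ids,
            evidence_segments=segments,
            fine_label=label,
        )
        instances.append(inst)
        retrieval_gold[instance_id] = planted_sids

    return SyntheticCorpus(documents, instances, retrieval_gold, config)


# ---------------------------------------------------------------------------
# Plant verification
# ---------------------------------------------------------------------------


def plant_check(corpus: SyntheticCorpus) -> list[tuple[str, str]]:
    """Verify instance invariants and label-conditional construction rules.

    Returns a list of (instance_id, violation) pairs; empty for a healthy
    corpus.
    """
    from .accuracy_classification import _negation_parity  # shared cue inventory

    violations: list[tuple[str, str]] = []
    for inst in corpus.instances:
        doc = corpus.documents.get(inst.reference_doc_id)
        if doc is None:
            violations.append((inst.instance_id, "unknown reference document"))
            continue
        for problem in inst.validate(doc):
            violations.append((inst.instance_id, problem))
        planted = corpus.retrieval_gold.get(inst.instance_id, [])
        for sid in planted:
            if sid not in doc.sentences:
                violations.append((inst.instance_id, f"dangling planted sentence {sid}"))
        if inst.fine_label is FineLabel.ETIQUETTE:
            if inst.marker_multiplicity != "multi":
                violations.append((inst.instance_id, "ETIQUETTE marker not multi"))
        if not planted:
            continue
        primary = doc.sentences[planted[0]].text
        s, e = inst.marker_span
        citance_text = inst.paragraph_text  # parity/number cues are local anyway
        if inst.fine_label is FineLabel.INDIRECT:
            if not locate_markers(primary):
                violations.append(
                    (inst.instance_id, "INDIRECT evidence lacks a citation marker")
                )
        if inst.fine_label is FineLabel.CONTRADICT:
            sents = segment_sentences(inst.paragraph_text)
            citance = next(t for t in sents if t.start <= s < t.end)
            if _negation_parity(citance.text) == _negation_parity(primary):
                violations.append(
                    (inst.instance_id, "CONTRADICT citance lacks polarity flip")
                )
        if inst.fine_label is FineLabel.MISQUOTE:
            sents = segment_sentences(inst.paragraph_text)
            citance = next(t for t in sents if t.start <= s < t.end)
            c_nums = set(extract_numbers(citance.text)) - set(
                extract_numbers(citance.text[s - citance.start : e - citance.start])
            )
            if set(extract_numbers(primary)) & c_nums == set(c_nums) and c_nums:
                violations.append(
                    (inst.instance_id, "MISQUOTE number not perturbed")
                )
    return violations


def consolidated_distribution(corpus: SyntheticCorpus) -> dict[str, int]:
    """Coarse-label counts, as pushed through the consolidation mapping."""
    counts: dict[str, int] = {}
    for inst in corpus.instances:
        key = consolidate_label(inst.fine_label).value
        counts[key] = counts.get(key, 0) + 1
    return counts
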