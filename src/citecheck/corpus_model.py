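"""Label taxonomy, citation data model, and corpus-level statistics.

A *citation instance* is one citation marker in a citing paragraph, linked
to the reference article it cites.  Each instance carries one of eight
fine-grained accuracy labels: ACCURATE, three major error categories
(CONTRADICT, NOT_SUBSTANTIATE, IRRELEVANT) and four minor ones
(OVERSIMPLIFY, MISQUOTE, INDIRECT, ETIQUETTE).  The error categories form a
strict priority order — a citation exhibiting several error types is
labeled with the highest-priority one.  For model training and evaluation
the eight labels collapse onto three coarse classes (ACCURATE /
NOT_ACCURATE / IRRELEVANT), mirroring the Support / Refute / Not-Enough-
Information scheme of scientific claim verification; notably INDIRECT — a
minor error where the reference is not the original source — is merged with
ACCURATE because such citations usually reflect the reference content
faithfully.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Optional

from .textutils import segment_sentences, sentence_index_at

__all__ = [
    "Severity",
    "FineLabel",
    "CoarseLabel",
    "TaxonomyError",
    "consolidate_label",
    "select_priority_label",
    "Span",
    "EvidenceSegment",
    "Sentence",
    "ReferenceDocument",
    "CitationInstance",
    "CorpusStatistics",
    "corpus_statistics",
    "statistics_from_counts",
]


class TaxonomyError(ValueError):
    """Unknown label name or invalid label-set usage."""


class Severity(enum.Enum):
    NONE = "NONE"
    MAJOR = "MAJOR"
    MINOR = "MINOR"


class FineLabel(enum.Enum):
    """The eight fine-grained citation accuracy categories."""

    ACCURATE = "ACCURATE"
    CONTRADICT = "CONTRADICT"
    NOT_SUBSTANTIATE = "NOT_SUBSTANTIATE"
    IRRELEVANT = "IRRELEVANT"
    OVERSIMPLIFY = "OVERSIMPLIFY"
    MISQUOTE = "MISQUOTE"
    INDIRECT = "INDIRECT"
    ETIQUETTE = "ETIQUETTE"

    @property
    def severity(self) -> Severity:
        if self is FineLabel.ACCURATE:
            return Severity.NONE
        if self in _MAJOR:
            return Severity.MAJOR
        return Severity.MINOR

    @property
    def priority_rank(self) -> Optional[int]:
        """1 = most severe error; ``None`` for ACCURATE (not an error)."""
        return _PRIORITY.get(self)

    @property
    def is_error(self) -> bool:
        return self is not FineLabel.ACCURATE


_MAJOR = frozenset(
    {FineLabel.CONTRADICT, FineLabel.NOT_SUBSTANTIATE, FineLabel.IRRELEVANT}
)

# Listing order of the error categories, most severe first.
_PRIORITY: dict[FineLabel, int] = {
    FineLabel.CONTRADICT: 1,
    FineLabel.NOT_SUBSTANTIATE: 2,
    FineLabel.IRRELEVANT: 3,
    FineLabel.OVERSIMPLIFY: 4,
    FineLabel.MISQUOTE: 5,
    FineLabel.INDIRECT: 6,
    FineLabel.ETIQUETTE: 7,
}

#: Fine labels that by definition carry no evidence segments.
EVIDENCE_FREE_LABELS = frozenset({FineLabel.IRRELEVANT, FineLabel.ETIQUETTE})


class CoarseLabel(enum.Enum):
    """Three-way consolidation used for training and evaluation."""

    ACCURATE = "ACCURATE"
    NOT_ACCURATE = "NOT_ACCURATE"
    IRRELEVANT = "IRRELEVANT"


_CONSOLIDATION: dict[FineLabel, CoarseLabel] = {
    FineLabel.ACCURATE: CoarseLabel.ACCURATE,
    FineLabel.INDIRECT: CoarseLabel.ACCURATE,
    FineLabel.CONTRADICT: CoarseLabel.NOT_ACCURATE,
    FineLabel.NOT_SUBSTANTIATE: CoarseLabel.NOT_ACCURATE,
    FineLabel.OVERSIMPLIFY: CoarseLabel.NOT_ACCURATE,
    FineLabel.MISQUOTE: CoarseLabel.NOT_ACCURATE,
    FineLabel.ETIQUETTE: CoarseLabel.NOT_ACCURATE,
    FineLabel.IRRELEVANT: CoarseLabel.IRRELEVANT,
}


def consolidate_label(fine: FineLabel | str) -> CoarseLabel:
    """Map a fine label onto its three-way coarse class.

    ACCURATE and INDIRECT map to ACCURATE; CONTRADICT, NOT_SUBSTANTIATE,
    OVERSIMPLIFY, MISQUOTE and ETIQUETTE to NOT_ACCURATE; IRRELEVANT to
    IRRELEVANT.
    """
    if isinstance(fine, str):
        try:
            fine = FineLabel(fine)
        except ValueError as exc:
            raise TaxonomyError(f"unknown fine label: {fine!r}") from exc
    return _CONSOLIDATION[fine]


def select_priority_label(applicable: Iterable[FineLabel]) -> FineLabel:
    """Pick the label to assign when several categories apply.

    Returns the applicable error with the smallest ``priority_rank``;
    ACCURATE is returned only when it is the sole applicable label.
    """
    labels = set(applicable)
    if not labels:
        raise TaxonomyError("select_priority_label requires a non-empty set")
    errors = [lab for lab in labels if lab.is_error]
    if not errors:
        return FineLabel.ACCURATE
    return min(errors, key=lambda lab: _PRIORITY[lab])


# ---------------------------------------------------------------------------
# Document and instance containers
# ---------------------------------------------------------------------------

Span = tuple[int, int]  # 0-based half-open character interval


class Sentence(NamedTuple):
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class EvidenceSegment:
    """A sentence, paragraph, or section of the reference article that the
    citation context is asserted against."""

    reference_doc_id: str
    granularity: str  # "sentence" | "paragraph" | "section"
    unit_id: str

    def __post_init__(self) -> None:
        if self.granularity not in ("sentence", "paragraph", "section"):
            raise ValueError(f"bad granularity: {self.granularity!r}")


@dataclass
class ReferenceDocument:
    """Reference article as ordered sections -> paragraphs -> sentences.

    ``sentences`` maps stable sentence ids to (text, start, end) in the
    reconstructed full text; ids are totally ordered by document position.
    """

    doc_id: str
    title: str
    abstract_sentence_ids: list[str]
    sections: list[tuple[str, str, list[str]]]  # (section_id, heading, paragraph_ids)
    paragraphs: dict[str, list[str]]  # paragraph_id -> ordered sentence ids
    sentences: dict[str, Sentence]  # sentence_id -> (text, start, end)

    def ordered_sentence_ids(self) -> list[str]:
        out: list[str] = []
        for _sec_id, _heading, par_ids in self.sections:
            for pid in par_ids:
                out.extend(self.paragraphs[pid])
        return out

    def full_text(self) -> str:
        ids = self.ordered_sentence_ids()
        if not ids:
            return ""
        end = max(self.sentences[sid].end for sid in ids)
        buf = [" "] * end
        for sid in ids:
            sent = self.sentences[sid]
            buf[sent.start : sent.end] = sent.text
        return "".join(buf)

    def section_of(self, sentence_id: str) -> str:
        for sec_id, _h, par_ids in self.sections:
            for pid in par_ids:
                if sentence_id in self.paragraphs[pid]:
                    return sec_id
        raise KeyError(sentence_id)

    def paragraph_of(self, sentence_id: str) -> str:
        for pid, sids in self.paragraphs.items():
            if sentence_id in sids:
                return pid
        raise KeyError(sentence_id)

    def expand_unit(self, granularity: str, unit_id: str) -> list[str]:
        """Sentence ids of the named unit, in document order."""
        if granularity == "sentence":
            if unit_id not in self.sentences:
                raise KeyError(f"sentence {unit_id!r} not in {self.doc_id}")
            return [unit_id]
        if granularity == "paragraph":
            if unit_id not in self.paragraphs:
                raise KeyError(f"paragraph {unit_id!r} not in {self.doc_id}")
            return list(self.paragraphs[unit_id])
        if granularity == "section":
            for sec_id, _h, par_ids in self.sections:
                if sec_id == unit_id:
                    out: list[str] = []
                    for pid in par_ids:
                        out.extend(self.paragraphs[pid])
                    return out
            raise KeyError(f"section {unit_id!r} not in {self.doc_id}")
        raise ValueError(f"bad granularity: {granularity!r}")

    def validate(self) -> None:
        ids = self.ordered_sentence_ids()
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.doc_id}: duplicate sentence ids")
        if set(ids) != set(self.sentences):
            raise ValueError(f"{self.doc_id}: tree/sentence-map mismatch")
        starts = [self.sentences[sid].start for sid in ids]
        if starts != sorted(starts):
            raise ValueError(f"{self.doc_id}: sentence ids not document-ordered")


@dataclass
class CitationInstance:
    """One citation marker in context, with its gold annotation.

    ``coarse_label`` is always derived from ``fine_label`` via
    :func:`consolidate_label`; it is exposed as a property so the two can
    never drift apart.
    """

    instance_id: str
    citing_doc_id: str
    reference_doc_id: str
    paragraph_text: str
    marker_span: Span
    marker_multiplicity: str  # "single" | "multi"
    other_marker_spans: list[Span]
    context_sentence_ids: list[int]  # paragraph-local sentence indices
    evidence_segments: list[EvidenceSegment]
    fine_label: FineLabel

    @property
    def coarse_label(self) -> CoarseLabel:
        return consolidate_label(self.fine_label)

    def citance_index(self) -> int:
        """Paragraph-local index of the sentence containing the marker."""
        sents = segment_sentences(self.paragraph_text)
        return sentence_index_at(sents, self.marker_span[0])

    def validate(self, doc: ReferenceDocument | None = None) -> list[str]:
        """Check structural invariants; returns human-readable violations."""
        problems: list[str] = []
        s, e = self.marker_span
        if not (0 <= s < e <= len(self.paragraph_text)):
            problems.append("marker_span outside paragraph_text")
        for os_, oe in self.other_marker_spans:
            if max(s, os_) < min(e, oe):
                problems.append("marker_span overlaps an other_marker_span")
        if self.marker_multiplicity not in ("single", "multi"):
            problems.append(f"bad multiplicity {self.marker_multiplicity!r}")
        if not problems:
            if self.citance_index() not in self.context_sentence_ids:
                problems.append("citance not in context_sentence_ids")
        if self.fine_label in EVIDENCE_FREE_LABELS:
            if self.evidence_segments:
                problems.append(
                    f"{self.fine_label.value} instance carries evidence segments"
                )
        else:
            if not self.evidence_segments:
                problems.append(
                    f"{self.fine_label.value} instance has no evidence segments"
                )
        if len(self.evidence_segments) > 5:
            problems.append("more than 5 evidence segments")
        if doc is not None:
            for seg in self.evidence_segments:
                if seg.reference_doc_id != doc.doc_id:
                    problems.append("evidence segment points at a different document")
                    continue
                try:
                    doc.expand_unit(seg.granularity, seg.unit_id)
                except (KeyError, ValueError) as exc:
                    problems.append(f"dangling evidence unit: {exc}")
        return problems


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------


def _round2(value: float) -> float:
    """Round half-up to 2 decimals (the convention of printed tables)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CorpusStatistics:
    """Corpus-level label distribution and per-citation ratios.

    Percentages are rounded half-up to 2 decimals.  ``group_percent`` holds
    the ACCURATE share plus the MAJOR / MINOR / TOTAL_ERRORS error groups.
    ``context_per_citation`` / ``evidence_per_citation`` are flagged
    undefined (None) for an empty corpus.
    """

    n_instances: int
    n_context_sentences: int
    n_evidence_sentences: int
    per_label_counts: dict[FineLabel, int]
    per_label_percent: dict[FineLabel, float]
    group_percent: dict[str, float]
    context_per_citation: Optional[float]
    evidence_per_citation: Optional[float]
    flags: list[str] = field(default_factory=list)


def statistics_from_counts(
    per_label_counts: Mapping[FineLabel, int],
    n_context_sentences: int,
    n_evidence_sentences: int,
) -> CorpusStatistics:
    """Build a :class:`CorpusStatistics` report from raw counts."""
    counts = {lab: int(per_label_counts.get(lab, 0)) for lab in FineLabel}
    n = sum(counts.values())
    flags: list[str] = []
    if n == 0:
        flags.append("empty corpus: ratios undefined")
        return CorpusStatistics(
            n_instances=0,
            n_context_sentences=n_context_sentences,
            n_evidence_sentences=n_evidence_sentences,
            per_label_counts=counts,
            per_label_percent={lab: 0.0 for lab in FineLabel},
            group_percent={k: 0.0 for k in ("ACCURATE", "MAJOR", "MINOR", "TOTAL_ERRORS")},
            context_per_citation=None,
            evidence_per_citation=None,
            flags=flags,
        )
    pct = {lab: _round2(100.0 * c / n) for lab, c in counts.items()}
    major = sum(c for lab, c in counts.items() if lab.severity is Severity.MAJOR)
    minor = sum(c for lab, c in counts.items() if lab.severity is Severity.MINOR)
    group = {
        "ACCURATE": _round2(100.0 * counts[FineLabel.ACCURATE] / n),
        "MAJOR": _round2(100.0 * major / n),
        "MINOR": _round2(100.0 * minor / n),
        "TOTAL_ERRORS": _round2(100.0 * (major + minor) / n),
    }
    return CorpusStatistics(
        n_instances=n,
        n_context_sentences=n_context_sentences,
        n_evidence_sentences=n_evidence_sentences,
        per_label_counts=counts,
        per_label_percent=pct,
        group_percent=group,
        context_per_citation=_round2(n_context_sentences / n),
        evidence_per_citation=_round2(n_evidence_sentences / n),
        flags=flags,
    )


def corpus_statistics(
    instances: Iterable[CitationInstance],
    reference_docs: Mapping[str, ReferenceDocument] | None = None,
) -> CorpusStatistics:
    """Label distribution and per-citation sentence ratios for a corpus.

    Evidence sentences are counted by expanding each evidence segment to its
    member sentences when ``reference_docs`` is supplied; without documents,
    each segment counts as one sentence and the report is flagged.
    """
    counts: dict[FineLabel, int] = {lab: 0 for lab in FineLabel}
    n_context = 0
    n_evidence = 0
    flagged_unexpanded = False
    seen_evidence: set[tuple[str, str]] = set()
    for inst in instances:
        counts[inst.fine_label] += 1
        n_context += len(inst.context_sentence_ids)
        seen_evidence.clear()
        for seg in inst.evidence_segments:
            if reference_docs is not None and seg.reference_doc_id in reference_docs:
                doc = reference_docs[seg.reference_doc_id]
                for sid in doc.expand_unit(seg.granularity, seg.unit_id):
                    seen_evidence.add((seg.reference_doc_id, sid))
            else:
                if reference_docs is not None:
                    raise KeyError(f"unknown reference doc {seg.reference_doc_id!r}")
                flagged_unexpanded = True
                seen_evidence.add((seg.reference_doc_id, f"{seg.granularity}:{seg.unit_id}"))
        n_evidence += len(seen_evidence)
    stats = statistics_from_counts(counts, n_context, n_evidence)
    if flagged_unexpanded:
        stats.flags.append("evidence segments counted without expansion (no documents)")
    return stats
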