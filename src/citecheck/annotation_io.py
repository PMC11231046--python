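"""Annotation I/O: brat standoff files, citation-marker handling, JSONL corpus.

Brat standoff keeps annotations in a ``.ann`` file anchored to the source
``.txt`` by 0-based half-open character offsets.  Only the record types the
corpus needs are supported: text-bound entities (``T`` lines, discontinuous
spans joined by ``;``) and attributes (``A`` lines, which carry the fine
accuracy label).  The JSONL dialect serializes one citation instance or one
reference document per line; its schema is documented in
``docs/jsonl_schema.md``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence, TextIO

from .corpus_model import (
    CitationInstance,
    EvidenceSegment,
    FineLabel,
    ReferenceDocument,
    Sentence,
    Span,
)

__all__ = [
    "StandoffParseError",
    "StandoffEntity",
    "StandoffAttribute",
    "StandoffDocument",
    "parse_standoff",
    "write_standoff",
    "MarkerMatch",
    "DEFAULT_MARKER_PATTERNS",
    "locate_markers",
    "mask_markers",
    "expand_segment_to_sentences",
    "instance_to_dict",
    "instance_from_dict",
    "document_to_dict",
    "document_from_dict",
    "write_instances_jsonl",
    "read_instances_jsonl",
    "write_documents_jsonl",
    "read_documents_jsonl",
]


class StandoffParseError(ValueError):
    """Malformed standoff record; message names the offending line."""


class StandoffEntity(NamedTuple):
    entity_id: str
    label: str
    spans: tuple[Span, ...]
    surface: str


class StandoffAttribute(NamedTuple):
    attribute_id: str
    name: str
    target: str
    value: str


@dataclass
class StandoffDocument:
    """A source text plus its standoff entities and attributes."""

    text: str
    entities: list[StandoffEntity] = field(default_factory=list)
    attributes: list[StandoffAttribute] = field(default_factory=list)

    def entity(self, entity_id: str) -> StandoffEntity:
        for ent in self.entities:
            if ent.entity_id == entity_id:
                return ent
        raise KeyError(entity_id)


def _surface_of(text: str, spans: Sequence[Span]) -> str:
    # brat joins discontinuous fragments with a single space
    return " ".join(text[s:e] for s, e in spans)


def parse_standoff(txt: str, ann: str) -> StandoffDocument:
    """Parse brat ``.txt`` + ``.ann`` content into a :class:`StandoffDocument`.

    Raises :class:`StandoffParseError` for offsets outside the text, a
    surface string that does not match the text slice, or a duplicate id;
    the error message names the line.
    """
    doc = StandoffDocument(text=txt)
    seen: set[str] = set()
    for lineno, raw in enumerate(ann.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        rec_id = parts[0]
        if rec_id in seen:
            raise StandoffParseError(f"line {lineno}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        if rec_id.startswith("T"):
            if len(parts) < 3:
                raise StandoffParseError(f"line {lineno}: T record needs 3 fields")
            header, surface = parts[1], "\t".join(parts[2:])
            label, _, span_part = header.partition(" ")
            spans: list[Span] = []
            for frag in span_part.split(";"):
                try:
                    s_str, e_str = frag.split()
                    s, e = int(s_str), int(e_str)
                except ValueError as exc:
                    raise StandoffParseError(
                        f"line {lineno}: bad span fragment {frag!r}"
                    ) from exc
                if not (0 <= s <= e <= len(txt)):
                    raise StandoffParseError(
                        f"line {lineno}: span {s}..{e} outside text (len {len(txt)})"
                    )
                spans.append((s, e))
            expected = _surface_of(txt, spans)
            if surface != expected:
                raise StandoffParseError(
                    f"line {lineno}: surface text {surface!r} != text slice {expected!r}"
                )
            doc.entities.append(StandoffEntity(rec_id, label, tuple(spans), surface))
        elif rec_id.startswith("A"):
            if len(parts) != 2:
                raise StandoffParseError(f"line {lineno}: A record needs 2 fields")
            fields = parts[1].split(" ")
            if len(fields) == 2:  # binary attribute
                name, target = fields
                value = "true"
            elif len(fields) == 3:
                name, target, value = fields
            else:
                raise StandoffParseError(f"line {lineno}: bad A record")
            doc.attributes.append(StandoffAttribute(rec_id, name, target, value))
        else:
            raise StandoffParseError(
                f"line {lineno}: unsupported record type {rec_id[0]!r}"
            )
    return doc


def write_standoff(doc: StandoffDocument) -> tuple[str, str]:
    """Render a :class:`StandoffDocument` back to ``(txt, ann)`` content."""
    lines: list[str] = []
    for ent in doc.entities:
        span_part = ";".join(f"{s} {e}" for s, e in ent.spans)
        lines.append(f"{ent.entity_id}\t{ent.label} {span_part}\t{ent.surface}")
    for attr in doc.attributes:
        lines.append(f"{attr.attribute_id}\t{attr.name} {attr.target} {attr.value}")
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return doc.text, ann


# ---------------------------------------------------------------------------
# Citation markers
# ---------------------------------------------------------------------------


class MarkerMatch(NamedTuple):
    span: Span
    multiplicity: str  # "single" | "multi"
    text: str


#: Default marker dialects, tried in order: bracketed numeric ("[3]",
#: "[2,4]", "[2-5]" with hyphen/en-dash/em-dash), author-year
#: ("(Smith et al., 2019)", possibly several refs separated by ";"), and
#: parenthesized numeric restricted to 1-3 digit numbers so that years like
#: "(2020)" are not mistaken for citations.
DEFAULT_MARKER_PATTERNS: tuple[str, ...] = (
    r"\[\s*\d{1,3}\s*(?:[,;–—-]\s*\d{1,3}\s*)*\]",
    r"\((?:[A-Z][\w'’-]+(?:\s+(?:and|&)\s+[A-Z][\w'’-]+)?"
    r"(?:\s+et\s+al\.?)?,?\s+\d{4}[a-z]?)"
    r"(?:;\s*[A-Z][\w'’-]+(?:\s+(?:and|&)\s+[A-Z][\w'’-]+)?"
    r"(?:\s+et\s+al\.?)?,?\s+\d{4}[a-z]?)*\)",
    r"\(\s*\d{1,3}\s*(?:[,;–—-]\s*\d{1,3}\s*)*\)",
)

_RANGE_OR_LIST = re.compile(r"\d\s*[,;–—-]\s*\d|;")


def _is_multi(marker_text: str) -> bool:
    return bool(_RANGE_OR_LIST.search(marker_text))


def locate_markers(
    paragraph: str, patterns: Sequence[str] = DEFAULT_MARKER_PATTERNS
) -> list[MarkerMatch]:
    """Find citation markers in a paragraph.

    Returns non-overlapping matches sorted by position.  Multiplicity is
    ``multi`` when the marker encloses more than one reference (a range like
    "[2-5]", a comma list, or several author-year citations).  Zero matches
    is a valid result.
    """
    candidates: list[tuple[int, Span, str]] = []
    for prio, pat in enumerate(patterns):
        for m in re.finditer(pat, paragraph):
            candidates.append((prio, (m.start(), m.end()), m.group(0)))
    candidates.sort(key=lambda c: (c[1][0], c[0], -(c[1][1] - c[1][0])))
    out: list[MarkerMatch] = []
    occupied_end = -1
    for _prio, (s, e), text in candidates:
        if s < occupied_end:
            continue
        out.append(MarkerMatch((s, e), "multi" if _is_multi(text) else "single", text))
        occupied_end = e
    return out


def mask_markers(
    sentence: str, target: Span | None, others: Sequence[Span] = ()
) -> str:
    """Replace citation markers with mask tokens.

    The target marker becomes ``[cit]`` (or ``[multi_cit]`` when it encloses
    multiple references); every other marker becomes ``[other_cit]``.
    Replacements are applied right-to-left so earlier offsets stay valid.
    ``target`` may be None when masking a non-citance sentence.
    """
    spans: list[tuple[Span, str]] = []
    if target is not None:
        s, e = target
        if not (0 <= s < e <= len(sentence)):
            raise ValueError(f"target span {target} outside sentence")
        token = "[multi_cit]" if _is_multi(sentence[s:e]) else "[cit]"
        spans.append(((s, e), token))
    for sp in others:
        s, e = sp
        if not (0 <= s < e <= len(sentence)):
            raise ValueError(f"marker span {sp} outside sentence")
        spans.append(((s, e), "[other_cit]"))
    spans.sort(key=lambda item: item[0][0])
    for ((_, e1), _t1), ((s2, _), _t2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping marker spans")
    out = sentence
    for (s, e), token in reversed(spans):
        out = out[:s] + token + out[e:]
    return out


def expand_segment_to_sentences(
    seg: EvidenceSegment, doc: ReferenceDocument
) -> list[str]:
    """Sentence ids covered by an evidence segment, in document order.

    A sentence-granularity segment yields its own id; paragraph and section
    segments yield every member sentence id.  A dangling unit id raises
    ``KeyError``.
    """
    if seg.reference_doc_id != doc.doc_id:
        raise KeyError(
            f"segment targets {seg.reference_doc_id!r}, got document {doc.doc_id!r}"
        )
    return doc.expand_unit(seg.granularity, seg.unit_id)


# ---------------------------------------------------------------------------
# JSONL corpus dialect
# ---------------------------------------------------------------------------


def instance_to_dict(inst: CitationInstance) -> dict:
    return {
        "instance_id": inst.instance_id,
        "citing_doc_id": inst.citing_doc_id,
        "reference_doc_id": inst.reference_doc_id,
        "paragraph_text": inst.paragraph_text,
        "marker_span": list(inst.marker_span),
        "marker_multiplicity": inst.marker_multiplicity,
        "other_marker_spans": [list(sp) for sp in inst.other_marker_spans],
        "context_sentence_ids": list(inst.context_sentence_ids),
        "evidence_segments": [
            {
                "reference_doc_id": seg.reference_doc_id,
                "granularity": seg.granularity,
                "unit_id": seg.unit_id,
            }
            for seg in inst.evidence_segments
        ],
        "fine_label": inst.fine_label.value,
        "coarse_label": inst.coarse_label.value,  # derived, written for readers
    }


def instance_from_dict(data: dict) -> CitationInstance:
    return CitationInstance(
        instance_id=data["instance_id"],
        citing_doc_id=data["citing_doc_id"],
        reference_doc_id=data["reference_doc_id"],
        paragraph_text=data["paragraph_text"],
        marker_span=tuple(data["marker_span"]),
        marker_multiplicity=data["marker_multiplicity"],
        other_marker_spans=[tuple(sp) for sp in data.get("other_marker_spans", [])],
        context_sentence_ids=list(data["context_sentence_ids"]),
        evidence_segments=[
            EvidenceSegment(
                reference_doc_id=seg["reference_doc_id"],
                granularity=seg["granularity"],
                unit_id=seg["unit_id"],
            )
            for seg in data.get("evidence_segments", [])
        ],
        fine_label=FineLabel(data["fine_label"]),
    )


def document_to_dict(doc: ReferenceDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "title": doc.title,
        "abstract_sentence_ids": list(doc.abstract_sentence_ids),
        "sections": [
            {"section_id": sid, "heading": heading, "paragraph_ids": list(pids)}
            for sid, heading, pids in doc.sections
        ],
        "paragraphs": {pid: list(sids) for pid, sids in doc.paragraphs.items()},
        "sentences": {
            sid: {"text": s.text, "start": s.start, "end": s.end}
            for sid, s in doc.sentences.items()
        },
    }


def document_from_dict(data: dict) -> ReferenceDocument:
    return ReferenceDocument(
        doc_id=data["doc_id"],
        title=data["title"],
        abstract_sentence_ids=list(data["abstract_sentence_ids"]),
        sections=[
            (sec["section_id"], sec["heading"], list(sec["paragraph_ids"]))
            for sec in data["sections"]
        ],
        paragraphs={pid: list(sids) for pid, sids in data["paragraphs"].items()},
        sentences={
            sid: Sentence(s["text"], s["start"], s["end"])
            for sid, s in data["sentences"].items()
        },
    )


def write_instances_jsonl(instances: Iterable[CitationInstance], fh: TextIO) -> int:
    n = 0
    for inst in instances:
        fh.write(json.dumps(instance_to_dict(inst), sort_keys=True) + "\n")
        n += 1
    return n


def read_instances_jsonl(fh: TextIO) -> list[CitationInstance]:
    return [instance_from_dict(json.loads(line)) for line in fh if line.strip()]


def write_documents_jsonl(docs: Iterable[ReferenceDocument], fh: TextIO) -> int:
    n = 0
    for doc in docs:
        fh.write(json.dumps(document_to_dict(doc), sort_keys=True) + "\n")
        n += 1
    return n


def read_documents_jsonl(fh: TextIO) -> list[ReferenceDocument]:
    return [document_from_dict(json.loads(line)) for line in fh if line.strip()]
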