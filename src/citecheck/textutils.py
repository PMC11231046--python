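"""Low-level text primitives shared by every pipeline stage.

Tokenization is deliberately simple — lowercase alphanumeric terms with a
small English stopword list — because the retrieval and verification stages
are lexical models whose behaviour must be auditable.  Sentence segmentation
is a rule-based splitter that protects the abbreviations common in
biomedical prose (``et al.``, ``e.g.``, ``Fig.`` ...) so that citances such
as ``Smith et al. (2020) showed X.`` survive as single sentences.
"""

from __future__ import annotations

import re
from typing import NamedTuple

#: Citation-marker mask tokens inserted by :func:`citecheck.annotation_io.mask_markers`.
MASK_TOKENS = frozenset({"cit", "multi_cit", "other_cit", "cls"})

#: Minimal English stopword list.  Negation words (not, no, never ...) are
#: deliberately EXCLUDED so that polarity cues survive tokenization.
STOPWORDS = frozenset(
    """a an the and or but if then than that this these those of in on at by
    for with to from as is are was were be been being it its their his her
    they them we our you your i he she who whom which what when where how
    also both each such same so too very can will just into over under
    between among during about against after before above below up down out
    off again further once here there all any more most other some only own
    do does did doing have has had having would should could may might must
    shall""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:_[a-z0-9]+)*")
_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")


def tokenize(text: str, *, drop_stopwords: bool = True) -> list[str]:
    """Lowercase alphanumeric tokens, with stopwords and mask tokens removed.

    Parameters
    ----------
    text : str
        Raw text; case and punctuation are discarded.
    drop_stopwords : bool
        When False only the mask tokens are removed (used by polarity checks
        that need function words preserved).
    """
    tokens = _TOKEN_RE.findall(text.lower())
    if drop_stopwords:
        return [t for t in tokens if t not in STOPWORDS and t not in MASK_TOKENS]
    return [t for t in tokens if t not in MASK_TOKENS]


def extract_numbers(text: str) -> list[str]:
    """All numeric literals in ``text``, as strings (``"45"``, ``"0.59"``)."""
    return _NUMBER_RE.findall(text)


class SegmentedSentence(NamedTuple):
    """One sentence of a segmented text, with its half-open character span."""

    index: int
    text: str
    start: int
    end: int


# Abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = (
    "et al.", "e.g.", "i.e.", "cf.", "vs.", "ca.", "approx.",
    "fig.", "figs.", "ref.", "refs.", "eq.", "eqs.", "no.", "nos.",
    "dr.", "mr.", "ms.", "prof.", "st.", "resp.",
)
_PLACEHOLDER = "\x00"
_BOUNDARY_RE = re.compile(r"[.!?]+[\"')\]]*\s+(?=[\"'(\[]?[A-Z0-9])")


def _protect(text: str) -> str:
    low = text.lower()
    out = list(text)
    for abbr in _ABBREVIATIONS:
        start = 0
        while True:
            i = low.find(abbr, start)
            if i < 0:
                break
            out[i + len(abbr) - 1] = _PLACEHOLDER
            start = i + len(abbr)
    return "".join(out)


def segment_sentences(text: str) -> list[SegmentedSentence]:
    """Split ``text`` into sentences with character offsets.

    Offsets are 0-based half-open into the original string; the concatenation
    of the returned slices covers every non-whitespace character of ``text``.
    An empty or all-whitespace input yields an empty list.
    """
    if not text or not text.strip():
        return []
    protected = _protect(text)
    cuts = [m.end() for m in _BOUNDARY_RE.finditer(protected)]
    spans: list[tuple[int, int]] = []
    prev = 0
    for cut in cuts + [len(text)]:
        raw = text[prev:cut]
        lstrip = len(raw) - len(raw.lstrip())
        rstrip = len(raw) - len(raw.rstrip())
        if raw.strip():
            spans.append((prev + lstrip, cut - rstrip))
        prev = cut
    return [
        SegmentedSentence(i, text[s:e], s, e) for i, (s, e) in enumerate(spans)
    ]


def sentence_index_at(sentences: list[SegmentedSentence], offset: int) -> int:
    """Index of the sentence whose span contains ``offset``.

    Offsets falling in inter-sentence whitespace are assigned to the next
    sentence; offsets past the last sentence to the last one.

    Raises
    ------
    ValueError
        If ``sentences`` is empty.
    """
    if not sentences:
        raise ValueError("no sentences to locate offset in")
    for sent in sentences:
        if offset < sent.end:
            return sent.index
    return sentences[-1].index
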