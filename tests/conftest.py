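"""Shared fixtures: hand-built reference documents and random factories."""

from __future__ import annotations

import random

import pytest

from citecheck.corpus_model import ReferenceDocument, Sentence


def make_doc(
    sentences: list[str],
    doc_id: str = "doc1",
    title: str = "A test document",
    paragraph_sizes: list[int] | None = None,
    sections: list[tuple[str, int]] | None = None,
    n_abstract: int = 0,
) -> ReferenceDocument:
    """Build a ReferenceDocument from a flat sentence list.

    ``paragraph_sizes`` carves the sentences into paragraphs (default: one
    paragraph); ``sections`` is a list of (heading, n_paragraphs) carving
    the paragraphs into sections (default: one section).  The first
    ``n_abstract`` sentences form the abstract.
    """
    if paragraph_sizes is None:
        paragraph_sizes = [len(sentences)]
    assert sum(paragraph_sizes) == len(sentences)
    sid_list = [f"{doc_id}:s{i:04d}" for i in range(len(sentences))]
    sent_map: dict[str, Sentence] = {}
    cursor = 0
    for sid, text in zip(sid_list, sentences):
        sent_map[sid] = Sentence(text, cursor, cursor + len(text))
        cursor += len(text) + 1
    paragraphs: dict[str, list[str]] = {}
    i = 0
    for p, size in enumerate(paragraph_sizes):
        paragraphs[f"{doc_id}:p{p:03d}"] = sid_list[i : i + size]
        i += size
    pids = list(paragraphs)
    if sections is None:
        sections = [("Body", len(pids))]
    sec_list: list[tuple[str, str, list[str]]] = []
    j = 0
    for s, (heading, n_par) in enumerate(sections):
        sec_list.append((f"{doc_id}:sec{s}", heading, pids[j : j + n_par]))
        j += n_par
    doc = ReferenceDocument(
        doc_id=doc_id,
        title=title,
        abstract_sentence_ids=sid_list[:n_abstract],
        sections=sec_list,
        paragraphs=paragraphs,
        sentences=sent_map,
    )
    doc.validate()
    return doc


WORDS = (
    "kinase enzyme pathway receptor tissue signal growth cell stress marker "
    "tumor liver neuron plasma serum membrane protein gene factor response "
    "binding uptake clearance infusion dosage assay model cohort trial outcome"
).split()


def random_doc(rng: random.Random, n_sentences: int, doc_id: str) -> ReferenceDocument:
    sentences = []
    for _ in range(n_sentences):
        n = rng.randint(3, 10)
        sentences.append(" ".join(rng.choice(WORDS) for _ in range(n)).capitalize() + ".")
    return make_doc(sentences, doc_id=doc_id)


@pytest.fixture
def toy_doc() -> ReferenceDocument:
    return make_doc(
        [
            "Insulin regulates glucose uptake in muscle.",
            "Leptin controls appetite through the hypothalamus.",
            "Cortisol elevates plasma glucose under stress.",
            "The assay used a standard cohort of mice.",
            "Receptor binding was measured by infusion.",
        ],
        paragraph_sizes=[3, 2],
        sections=[("Abstract", 1), ("Results", 1)],
        n_abstract=3,
    )
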