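# JSONL corpus dialect

Two line-oriented JSON files describe a corpus.  All character offsets are
0-based half-open intervals into the containing text.

## `instances.jsonl` — one citation instance per line

| key | type | meaning |
| --- | --- | --- |
| `instance_id` | string | opaque unique id |
| `citing_doc_id` | string | id of the citing article |
| `reference_doc_id` | string | id of the cited article |
| `paragraph_text` | string | citing paragraph containing the marker |
| `marker_span` | `[start, end]` | target citation marker offsets |
| `marker_multiplicity` | `"single" \| "multi"` | whether the marker encloses several references (`[2–5]`, `[1,3]`) |
| `other_marker_spans` | list of `[start, end]` | other citation markers in the paragraph |
| `context_sentence_ids` | list of int | paragraph-local sentence indices of the gold citation context; always contains the citance |
| `evidence_segments` | list of objects | 0–5 segments, empty iff the fine label is `IRRELEVANT` or `ETIQUETTE` |
| `fine_label` | string | one of the eight fine labels |
| `coarse_label` | string | derived three-way label (written for readers; recomputed on load) |

Each evidence segment object has `reference_doc_id`, `granularity`
(`"sentence" | "paragraph" | "section"`), and `unit_id` resolving in the
named reference document.

## `documents.jsonl` — one reference article per line

| key | type | meaning |
| --- | --- | --- |
| `doc_id` | string | unique article id |
| `title` | string | article title |
| `abstract_sentence_ids` | list | sentence ids of the abstract |
| `sections` | list of `{section_id, heading, paragraph_ids}` | ordered sections |
| `paragraphs` | map | paragraph id → ordered sentence ids |
| `sentences` | map | sentence id → `{text, start, end}` offsets in the reconstructed full text |

Sentence ids are unique and totally ordered by document position; every
sentence belongs to exactly one paragraph and one section.

## Generator extras

`citecheck make-fixtures` additionally writes `retrieval_gold.json`, a map
from `instance_id` to the planted (sentence-level) gold evidence sentence
ids used for retrieval evaluation.
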