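# citecheck

Citation-integrity screening for scientific literature.

A substantial fraction of citations in biomedical papers misrepresent the
work they cite — they contradict it, overstate it, misquote its numbers, or
cite it for something it never says.  `citecheck` implements the
computational side of citation-integrity assessment as a three-stage
pipeline over a *citing article* / *reference article* pair:

1. **Citation context identification** — in the citing paragraph, find the
   sentences discussing the cited reference.  The *citance* (the sentence
   containing the citation marker) is always part of the context, so the
   citance-only baseline has precision 1 by construction.
2. **Evidence sentence retrieval** — in the reference article, rank
   sentences by relevance to the citation context: Okapi BM25 over the
   article's own sentence collection retrieves the top 60 candidates, an
   optional cross-scorer reranks them, and the top *k* ∈ {5, 10, 20}
   sentences become the evidence set.  A title+abstract baseline is
   included.
3. **Citation accuracy classification** — treat the context as a claim and
   the evidence sentences as its source (the Support / Refute /
   Not-Enough-Information framing of claim verification) and assign one of
   three classes: `ACCURATE`, `NOT_ACCURATE`, `IRRELEVANT`.

Annotations use an eight-category quotation-error taxonomy with a strict
priority order: `ACCURATE`; major errors `CONTRADICT` ≻ `NOT_SUBSTANTIATE`
≻ `IRRELEVANT`; minor errors `OVERSIMPLIFY` ≻ `MISQUOTE` ≻ `INDIRECT` ≻
`ETIQUETTE`.  For training and evaluation the eight labels consolidate to
the three coarse classes (`ACCURATE`+`INDIRECT` → ACCURATE; the five
remaining errors → NOT_ACCURATE; `IRRELEVANT` → IRRELEVANT).

The package ships the data model and corpus statistics, brat-standoff and
JSONL annotation I/O, the three pipeline stages with pluggable backends
(including an in-context-learning prompt builder and a trainable
lexical-feature backend), the full evaluation suite (per-class and averaged
P/R/F1, recall@k, MRR, pairwise Cohen's κ, McNemar's test), and a seeded
synthetic corpus generator that plants evidence and label-specific
perturbations so every stage is testable without any downloads.

## The core quantities

For a query sentence set *q* and reference-article sentence *S*, BM25 with
parameters `k1 = 1.2`, `b = 0.75` scores

    score(S) = Σ_t idf(t) · tf(t,S)(k1+1) / (tf(t,S) + k1(1 − b + b·|S|/avgdl)),
    idf(t)   = ln(1 + (N − df(t) + 0.5)/(df(t) + 0.5)),

with *N* and *df* computed over the sentences of the single cited article.
Retrieval is scored by recall@k (fraction of gold evidence sentences in the
top *k*) and MRR with rank cutoff 20.  Classification is scored by
per-class and micro/macro F₁; paired systems are compared with McNemar's
exact binomial test (continuity-corrected χ² for ≥ 25 discordant pairs);
annotator agreement uses Cohen's κ = (p_o − p_e)/(1 − p_e).

## Worked example

```python
from citecheck import (
    FineLabel, statistics_from_counts,
    GeneratorConfig, generate_corpus,
    PipelineConfig, run_pipeline, evaluate_run,
)

# Corpus-level statistics from published annotation counts
stats = statistics_from_counts(
    {FineLabel.ACCURATE: 1863, FineLabel.CONTRADICT: 92,
     FineLabel.NOT_SUBSTANTIATE: 243, FineLabel.IRRELEVANT: 217,
     FineLabel.OVERSIMPLIFY: 111, FineLabel.MISQUOTE: 38,
     FineLabel.INDIRECT: 82, FineLabel.ETIQUETTE: 417},
    n_context_sentences=3420, n_evidence_sentences=3791,
)
print(stats.group_percent)
print(stats.context_per_citation, stats.evidence_per_citation)

# End-to-end pipeline on a seeded synthetic corpus
corpus = generate_corpus(GeneratorConfig(seed=1))
result = run_pipeline(corpus.documents, corpus.instances, PipelineConfig())
report, retrieval = evaluate_run(
    result.predictions, corpus.instances, result.rankings, corpus.retrieval_gold
)
print(round(report.micro_f1, 3), round(retrieval.recall_at[20], 3))
```

prints

```
{'ACCURATE': 60.82, 'MAJOR': 18.02, 'MINOR': 21.16, 'TOTAL_ERRORS': 39.18}
1.12 1.24
0.998 1.0
```

i.e. 60.82% of the 3063 annotated citations are accurate (39.18% carry an
error — 18.02% major, 21.16% minor), with 1.12 context and 1.24 evidence
sentences per citation; and on the default synthetic corpus the
citance → BM25 top-20 → heuristic-verifier pipeline recovers planted
evidence with recall@20 = 1.0 and classifies coarse labels at micro-F₁
0.998 (the planted perturbations are deliberately clean-cut; see
`docs/methods.md` for what this does and does not show).

The same pipeline is available from the shell:

```bash
citecheck make-fixtures --n-docs 20 --n-instances 500 --seed 7 --out fixtures/
citecheck run --instances fixtures/instances.jsonl --docs fixtures/documents.jsonl \
              --query-mode citance --top-k 20 --out run/
citecheck evaluate --task accuracy --gold fixtures/instances.jsonl \
                   --pred run/predictions.tsv
```

## Layout

- `src/citecheck/corpus_model.py` — taxonomy, data model, statistics
- `src/citecheck/annotation_io.py` — brat standoff + JSONL I/O, markers
- `src/citecheck/context_identification.py` — stage 1
- `src/citecheck/evidence_retrieval.py` — stage 2 (BM25, reranking)
- `src/citecheck/accuracy_classification.py` — stage 3 (backends, ICL)
- `src/citecheck/evaluation.py` — metrics and statistical tests
- `src/citecheck/synthetic_fixtures.py` — seeded corpus generator
- `src/citecheck/pipeline.py`, `src/citecheck/cli.py` — orchestration
- `docs/methods.md` — models, parameters, design choices, limitations
- `docs/jsonl_schema.md` — the JSONL corpus dialect
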