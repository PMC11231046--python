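# Methods

This note documents the models and procedures implemented in `citecheck`,
the parameters that matter, what the synthetic corpus generator emulates,
and the design decisions taken where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task and data model

A **citation instance** is one citation marker in a citing paragraph,
linked to one reference article.  The annotation unit mirrors common
annotation practice for this task: the citing paragraph with character-offset
marker spans (0-based, half-open — the brat standoff convention), a gold
citation context given as paragraph-local sentence indices, up to five
**evidence segments** in the reference article (each a sentence, a
paragraph, or a section), and a fine-grained accuracy label.

The eight fine labels split into no-error (`ACCURATE`), major errors
(`CONTRADICT`, `NOT_SUBSTANTIATE`, `IRRELEVANT`) and minor errors
(`OVERSIMPLIFY`, `MISQUOTE`, `INDIRECT`, `ETIQUETTE`).  The categories are
listed in priority order; when several apply, `select_priority_label`
returns the highest-priority (lowest-rank) error.  The listing order yields
ranks CONTRADICT=1 … ETIQUETTE=7; `ACCURATE` has no rank and is returned
only when it is the sole applicable label.  One consequence worth flagging:
a citation that is simultaneously irrelevant and etiquette-styled resolves
to `IRRELEVANT` (rank 3 beats rank 7); the taxonomy's source material does
not address this combination explicitly, so the listing order is applied
uniformly.

Coarse labels are *always derived*, never stored: `ACCURATE` and
`INDIRECT` map to coarse ACCURATE (an indirect citation typically reflects
the reference content faithfully even though the reference is not the
original source); `CONTRADICT`, `NOT_SUBSTANTIATE`, `OVERSIMPLIFY`,
`MISQUOTE` and `ETIQUETTE` map to NOT_ACCURATE; `IRRELEVANT` maps to
IRRELEVANT.

`evidence_segments` is empty exactly for `IRRELEVANT` and `ETIQUETTE`
instances — by definition those have no relevant or clearly identifiable
evidence.

Corpus statistics round percentages half-up to two decimals, matching the
convention of printed distribution tables.  With the published counts
(1863/92/243/217/111/38/82/417 over 3063 instances, 3420 context and 3791
evidence sentences) the module reproduces 60.82% accurate, 18.02% major,
21.16% minor, 39.18% total errors, and the per-citation ratios 1.12 and
1.24; the acceptance script recomputes this at every run.

## Stage 1 — context identification

Default method: the **citance baseline**, which predicts exactly the
sentence containing the target marker.  Because any gold context contains
the citance, the baseline's predicted set is a subset of gold and its
precision is structurally 1.0 — the test suite asserts this mechanism
rather than a particular corpus score.  This is also the pipeline default
because richer context brings little retrieval benefit at desk scale.

The classifier route scores each paragraph sentence against the citance
with a pluggable pair scorer on marker-masked text: the target marker
becomes `[cit]` (`[multi_cit]` when it encloses multiple references, e.g.
`[2–5]`), every other marker `[other_cit]`; replacements are applied
right-to-left so offsets stay valid, and mask tokens are invisible to
tokenization.  The bundled reference scorer is token Jaccard similarity
with threshold 0.5 — a transparent stand-in satisfying the same
`(sentence, citance) → [0,1]` contract a fine-tuned sentence-pair encoder
would implement.  Sub-sentence context spans can be stored in standoff
annotations, but prediction and evaluation operate at sentence level.

## Stage 2 — evidence retrieval

The retrieval collection is the sentence set of the *single cited article*
(the task has one known evidence source, so no cross-article index exists).
Okapi BM25 with `k1 = 1.2`, `b = 0.75` (standard defaults; the method
specification names BM25 without parameters) scores every sentence; IDF
uses `ln(1 + (N − df + 0.5)/(df + 0.5))`, non-negative for in-vocabulary
terms, with document frequency over the article's sentences.  Tokenization
is lowercase alphanumeric with a small English stopword list; negation
words are deliberately kept out of the stopword list because stage 3 needs
them.  Ties break by document position (earlier first).  A query with no
in-vocabulary terms yields all-zero scores, a document-order ranking, and
an `oov_query` flag rather than an error.

The first stage keeps `first_stage_n = 60` candidates; an optional
reranker reorders them, and the top `k ∈ {5, 10, 20}` (default 20) form
the evidence set.  The bundled reranker is an IDF-weighted token-overlap
cross-scorer — the plug-in contract `(query, sentence) → score` is exactly
what a neural cross-encoder reranker implements, so one can be registered
without touching the pipeline.  A failing reranker falls back to the BM25
order with a flag rather than aborting the stage.  Query modes: masked
citance (default), gold context sentences, gold context plus intervening
sentences, or the title+abstract baseline (title sentences then abstract
sentences, uniform scores).  Whether a second-stage reranker should reuse
the first-stage query is unspecified in the source method description; here
it does.

## Stage 3 — accuracy classification

Backends implement `(context, evidence, instance_id) → scores over the
three classes`; `classify` validates the contract (unknown labels raise),
normalizes scores to sum to 1, and guarantees the argmax equals the label.

The default **heuristic verifier** is a transparent rule cascade over the
IDF-weighted directional overlap between the masked context and each
evidence sentence (shared term weight / context term weight, using the
cited article's IDF):

1. no evidence, or best overlap < `low` → IRRELEVANT;
2. best overlap ≥ `high` with a negation-polarity or numeric mismatch
   against the best sentence → NOT_ACCURATE;
3. best overlap ≥ `high` otherwise → ACCURATE;
4. intermediate overlap → NOT_ACCURATE (related but not substantiating).

Thresholds `low = 0.1`, `high = 0.6` are package choices: `low` separates
"no lexical link" from "related", `high` separates "related" from
"restates".  Scores are derived from the margin to the nearest threshold
and normalized.  Negation polarity counts negation cues (`not`, `never`,
`without`, `fails`, `n't` …) mod 2; the numeric check fires when the
context quotes numbers not present in the best evidence sentence (the
mechanism behind misquoted percentages).  Empty evidence maps to
IRRELEVANT — the upstream annotation convention gives evidence-free gold
only to IRRELEVANT/ETIQUETTE items, and a verifier shown no evidence has
no basis to assert anything stronger.

`finetune_harness` produces a *trainable* backend under the same contract:
labels are consolidated 8→3 before fitting, and the rationale-selection
loss weight is pinned to 0 in the run manifest — evidence selection is
retrieval's job here, so the verifier learns label classification only.
The built-in model is a multinomial logistic regression over
overlap/polarity/numeric-mismatch features (scikit-learn); requesting a
neural architecture whose assets are not installed raises an explicit
"optional backend unavailable" error rather than silently substituting.

The in-context-learning path builds a deterministic prompt — task
instruction with three class descriptions, exactly four demonstrations
(one ACCURATE, two NOT_ACCURATE, one IRRELEVANT), then an unlabeled test
block, delimited by XML-like tags and markdown — and parses
`Label: <CLASS>` replies.  Generative-model prompts take only the top five
evidence sentences.  No live model calls occur anywhere in the package;
the path is exercised with canned replies.

## Evaluation

* **P/R/F1**: one-vs-rest per class; micro over pooled counts (equal to
  accuracy for single-label full-coverage predictions, asserted by a
  property test); macro unweighted over all listed classes, including
  zero-support ones (flagged).
* **recall@k** (`k ∈ {1,5,10,20}`) and **MRR** with rank cutoff 20.
  Instances with empty gold evidence are excluded from the averages and
  counted.  The standard MRR convention is used — higher means the first
  relevant sentence appears earlier.  (The source method text contains the
  phrase "low MRR [is] preferred", which contradicts that convention; the
  standard reading is implemented deliberately.)
* **Cohen's κ** from the closed form, with p_e = 1 reported as undefined
  (NaN) and flagged.  For context/evidence agreement the labelings are
  per-sentence binary membership vectors obtained by expanding segment
  annotations to sentences; the negative-class universe is the containing
  paragraph (context task) or the whole reference article (evidence task)
  — the choice of universe is a package decision, since sentence-level
  agreement needs an explicit negative class.
* **McNemar**: exact two-sided binomial on the discordant counts when
  b + c < 25, continuity-corrected χ² otherwise; b + c = 0 gives p = 1
  with a flag.

## Synthetic corpus generator

The generator is first-class, tested code.  It emulates the *structure* of
the task's inputs: reference articles of 50–300 sentences in titled
sections and paragraphs; citing paragraphs of 1–4 sentences containing one
target marker, occasional other markers, and occasional two-sentence gold
contexts (12%, giving ≈1.1 context sentences per citation, tracking the
annotated corpus's 1.12); 1–5 planted evidence segments per
evidence-bearing instance with weights (0.65, 0.20, 0.10, 0.03, 0.02)
(≈1.56 sentences per evidence-bearing citation, consistent with the
published totals 3791/(3063−634)); a granularity mix of 80% sentence / 15%
paragraph / 5% section to exercise segment expansion; and the published
label distribution as the default.

Each label is realized by a deliberately auditable perturbation of a
planted fact sentence: ACCURATE/INDIRECT copy its content words (INDIRECT
additionally plants a citation marker inside the evidence sentence);
CONTRADICT inserts a negation before the verb; MISQUOTE alters the quoted
percentage; NOT_SUBSTANTIATE/OVERSIMPLIFY keep about half of the content
words padded with claim words absent from the article; ETIQUETTE pairs a
multi-citation marker with a loosely related citance and no evidence;
IRRELEVANT draws from a disjoint off-topic vocabulary.  Word pools are
constructed so that claim padding never appears in reference articles —
this keeps the IDF-weighted overlap of each category inside its intended
band *by construction*, not by tuning.  `plant_check` re-verifies every
structural invariant and the label-conditional rules on any generated
corpus.

What passing tests show — and don't.  The generator's perturbations are
clean-cut and lexical, so the bundled pipeline separates the three classes
almost perfectly (the acceptance script prints micro-F₁ ≈ 1.0 at the
default conditions).  That validates the *plumbing and the pairing* —
retrieval finds planted evidence, the cascade's rules fire for the
constructions that should trigger them — and says nothing about real
scientific prose, where quotation errors are subtle, paraphrase is fluent,
and reported three-way F₁ for trained models sits far below 1.  The
generator makes no attempt to simulate realistic prose, annotator noise,
or non-exhaustive evidence annotation.

## Problem sizes and numerical choices

Default desk-scale conditions: 20 reference articles, 500 citation
instances, seeds threaded from a single integer through Python's
deterministic `random.Random`, so generation is a pure function of the
configuration.  BM25 score comparisons against the brute-force oracle are
exact to 1e-9; percentage rounding is half-up; all character offsets are
0-based half-open; retrieval ties break by document position; a marker
spanning a (mis-)detected sentence boundary is assigned to the sentence
containing its start, with a flag.

## Known limitations

* Sentence segmentation is rule-based with a fixed abbreviation list;
  pathological biomedical abbreviations can still split wrongly.
* The heuristic verifier is lexical: it cannot detect contradictions
  expressed without negation cues, paraphrased misquotes, or
  oversimplification expressed fluently.
* Marker dialect coverage (bracketed numeric, parenthesized numeric ≤ 3
  digits, author–year) is configurable but not exhaustive; superscript
  markers, for instance, are not recognized by default.
* Neural backends (sentence-pair encoder, cross-encoder reranker,
  long-input verifier) are plug-in contracts only; no weights ship with
  the package.
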