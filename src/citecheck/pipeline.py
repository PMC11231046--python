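"""End-to-end orchestration of the three pipeline stages.

``run_pipeline`` takes a corpus (reference documents + citation instances),
identifies the citation context of every instance, retrieves candidate
evidence sentences from the cited article, classifies citation accuracy,
and returns the stage outputs together with a run manifest sufficient to
re-execute the run bit-identically for deterministic backends.  Stage
outputs can be persisted as TSV; logs go to stderr and never mix with data
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__ as _pkg_version
from .accuracy_classification import (
    AccuracyPrediction,
    HeuristicVerifier,
    classify,
    finetune_harness,
    make_oracle_backend,
)
from .annotation_io import write_documents_jsonl, write_instances_jsonl
from .context_identification import (
    CONTEXT_SCORERS,
    ContextPrediction,
    citance_baseline,
    classify_context,
)
from .corpus_model import CitationInstance, CoarseLabel, ReferenceDocument
from .evaluation import EvalReport, RetrievalReport, prf_report, retrieval_report
from .evidence_retrieval import (
    RERANKERS,
    RankedEvidence,
    RetrievalConfig,
    SentenceIndex,
    bm25_rank,
    build_query,
    rerank,
    title_abstract_evidence,
)
from .annotation_io import expand_segment_to_sentences
from .textutils import segment_sentences

logger = logging.getLogger("citecheck")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "evaluate_run",
]

CONTEXT_METHODS = ("citance", "classifier")
CLASSIFIER_BACKENDS = ("heuristic", "oracle", "finetuned")


@dataclass(frozen=True)
class PipelineConfig:
    """One declarative configuration for an end-to-end run."""

    context_method: str = "citance"
    context_scorer: str = "jaccard"
    context_threshold: float = 0.5
    retrieval: RetrievalConfig = field(default_factory=RetrievalConfig)
    backend: str = "heuristic"
    heuristic_low: float = 0.1
    heuristic_high: float = 0.6
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.context_method not in CONTEXT_METHODS:
            raise ValueError(f"unknown context method {self.context_method!r}")
        if self.context_method == "classifier" and self.context_scorer not in CONTEXT_SCORERS:
            raise ValueError(f"unregistered context scorer {self.context_scorer!r}")
        if self.backend not in CLASSIFIER_BACKENDS:
            raise ValueError(f"unregistered backend {self.backend!r}")
        if (
            self.retrieval.reranker is not None
            and self.retrieval.reranker not in RERANKERS
        ):
            raise ValueError(f"unregistered reranker {self.retrieval.reranker!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    package_version: str
    input_digest: str
    stage_counts: dict[str, int]
    timing_s: dict[str, float]
    backend_manifest: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    context: dict[str, ContextPrediction]
    rankings: dict[str, RankedEvidence]
    predictions: dict[str, AccuracyPrediction]
    manifest: RunManifest


def _corpus_digest(
    documents: Mapping[str, ReferenceDocument], instances: Sequence[CitationInstance]
) -> str:
    buf = io.StringIO()
    write_documents_jsonl((documents[k] for k in sorted(documents)), buf)
    write_instances_jsonl(instances, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def run_pipeline(
    documents: Mapping[str, ReferenceDocument],
    instances: Sequence[CitationInstance],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    train_instances: Sequence[CitationInstance] | None = None,
) -> PipelineResult:
    """Execute context identification, evidence retrieval and accuracy
    classification for every instance.

    The ``oracle`` backend reads each instance's gold coarse label (a
    plumbing check, not a model).  The ``finetuned`` backend requires
    ``train_instances`` and fits the built-in lexical-feature model on
    them.  Stage errors are reported with the offending instance id;
    already-computed outputs are preserved in the raised error's
    ``partial`` attribute.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.WARNING))
    t0 = time.perf_counter()
    digest = _corpus_digest(documents, instances)
    indexes = {doc_id: SentenceIndex(doc) for doc_id, doc in documents.items()}

    timing: dict[str, float] = {}
    contexts: dict[str, ContextPrediction] = {}
    rankings: dict[str, RankedEvidence] = {}
    predictions: dict[str, AccuracyPrediction] = {}

    # ---- stage 1: context identification -------------------------------
    t = time.perf_counter()
    masked_contexts: dict[str, str] = {}
    for inst in instances:
        try:
            sents = segment_sentences(inst.paragraph_text)
            if config.context_method == "citance":
                pred = citance_baseline(sents, inst.marker_span, inst.instance_id)
            else:
                pred = classify_context(
                    sents,
                    inst.marker_span,
                    CONTEXT_SCORERS[config.context_scorer],
                    threshold=config.context_threshold,
                    other_marker_spans=inst.other_marker_spans,
                    instance_id=inst.instance_id,
                )
            contexts[inst.instance_id] = pred
            masked_contexts[inst.instance_id] = build_query(
                inst, "gold_context", context_sentence_ids=pred.sentence_ids
            )
        except Exception as exc:
            raise _stage_error("context", inst.instance_id, exc, contexts, rankings, predictions)
    timing["context"] = time.perf_counter() - t
    logger.info("context stage: %d instances", len(contexts))

    # ---- stage 2: evidence retrieval ------------------------------------
    t = time.perf_counter()
    rconf = config.retrieval
    for inst in instances:
        try:
            doc = documents[inst.reference_doc_id]
            if rconf.query_mode == "title_abstract":
                ranked = title_abstract_evidence(doc, inst.instance_id)
            else:
                if rconf.query_mode == "citance":
                    query = build_query(inst, "citance")
                elif rconf.query_mode in ("gold_context", "gold_context_with_intervening"):
                    query = build_query(inst, rconf.query_mode)
                else:  # pragma: no cover - config validated upstream
                    raise ValueError(rconf.query_mode)
                ranked = bm25_rank(
                    query, doc, rconf, inst.instance_id, index=indexes[inst.reference_doc_id]
                )
                if rconf.reranker is not None:
                    scorer = RERANKERS[rconf.reranker](indexes[inst.reference_doc_id])
                    ranked = rerank(ranked, query, doc, scorer)
                ranked.ranking = ranked.ranking[: rconf.top_k]
            rankings[inst.instance_id] = ranked
        except Exception as exc:
            raise _stage_error("retrieval", inst.instance_id, exc, contexts, rankings, predictions)
    timing["retrieval"] = time.perf_counter() - t
    logger.info("retrieval stage: %d instances", len(rankings))

    # ---- stage 3: accuracy classification --------------------------------
    t = time.perf_counter()
    backend_manifest: dict = {}
    if config.backend == "oracle":
        gold = {inst.instance_id: inst.coarse_label for inst in instances}
        backends = {None: make_oracle_backend(gold)}
        name = "oracle"
    elif config.backend == "finetuned":
        if train_instances is None:
            raise ValueError("finetuned backend requires train_instances")
        train_ev = {}
        train_ctx = {}
        for inst in train_instances:
            doc = documents[inst.reference_doc_id]
            sids: list[str] = []
            for seg in inst.evidence_segments:
                sids.extend(expand_segment_to_sentences(seg, doc))
            train_ev[inst.instance_id] = [doc.sentences[s].text for s in dict.fromkeys(sids)]
            train_ctx[inst.instance_id] = build_query(inst, "gold_context")
        backend, backend_manifest = finetune_harness(
            train_instances, {"model": "lexical-logreg"}, train_ev, train_ctx
        )
        backends = {None: backend}
        name = "finetuned"
    else:
        # one verifier per reference article so overlap uses that article's IDF
        backends = {
            doc_id: HeuristicVerifier(
                low=config.heuristic_low, high=config.heuristic_high, idf=idx.idf
            )
            for doc_id, idx in indexes.items()
        }
        name = "heuristic"
    for inst in instances:
        try:
            doc = documents[inst.reference_doc_id]
            ranked = rankings[inst.instance_id]
            evidence = [
                doc.sentences[sid].text
                for sid in ranked.sentence_ids()
                if sid in doc.sentences  # title pseudo-ids have no sentence entry
            ]
            backend = backends.get(inst.reference_doc_id) or backends[None]
            predictions[inst.instance_id] = classify(
                masked_contexts[inst.instance_id],
                evidence,
                backend,
                backend_name=name,
                instance_id=inst.instance_id,
            )
        except Exception as exc:
            raise _stage_error("classification", inst.instance_id, exc, contexts, rankings, predictions)
    timing["classification"] = time.perf_counter() - t
    timing["total"] = time.perf_counter() - t0
    logger.info("classification stage: %d instances", len(predictions))

    manifest = RunManifest(
        config=config.to_dict(),
        package_version=_pkg_version,
        input_digest=digest,
        stage_counts={
            "instances": len(instances),
            "context": len(contexts),
            "retrieval": len(rankings),
            "classification": len(predictions),
        },
        timing_s={k: round(v, 4) for k, v in timing.items()},
        backend_manifest=backend_manifest,
    )
    result = PipelineResult(contexts, rankings, predictions, manifest)
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


class StageError(RuntimeError):
    def __init__(self, stage: str, instance_id: str, cause: Exception, partial):
        super().__init__(f"{stage} stage failed on instance {instance_id!r}: {cause}")
        self.stage = stage
        self.instance_id = instance_id
        self.partial = partial


def _stage_error(stage, instance_id, exc, contexts, rankings, predictions) -> StageError:
    if isinstance(exc, StageError):
        return exc
    return StageError(stage, instance_id, exc, (contexts, rankings, predictions))


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "context.tsv", "w") as fh:
        fh.write("instance_id\tsentence_ids\tmethod\n")
        for pred in result.context.values():
            ids = ",".join(map(str, pred.sentence_ids))
            fh.write(f"{pred.instance_id}\t{ids}\t{pred.method}\n")
    with open(out_dir / "ranking.tsv", "w") as fh:
        fh.write("instance_id\trank\tsentence_id\tscore\tstage\n")
        for ranked in result.rankings.values():
            for rank, (sid, score) in enumerate(ranked.ranking, start=1):
                fh.write(f"{ranked.instance_id}\t{rank}\t{sid}\t{score:.6f}\t{ranked.stage}\n")
    with open(out_dir / "predictions.tsv", "w") as fh:
        fh.write("instance_id\tlabel\tp_accurate\tp_not_accurate\tp_irrelevant\tbackend\n")
        for pred in result.predictions.values():
            s = pred.score_per_label
            fh.write(
                f"{pred.instance_id}\t{pred.label.value}\t"
                f"{s[CoarseLabel.ACCURATE]:.6f}\t{s[CoarseLabel.NOT_ACCURATE]:.6f}\t"
                f"{s[CoarseLabel.IRRELEVANT]:.6f}\t{pred.backend}\n"
            )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(result.manifest), fh, indent=2, default=str)


def evaluate_run(
    predictions: Mapping[str, AccuracyPrediction],
    gold_instances: Sequence[CitationInstance],
    rankings: Mapping[str, RankedEvidence] | None = None,
    retrieval_gold: Mapping[str, Sequence[str]] | None = None,
) -> tuple[EvalReport, Optional[RetrievalReport]]:
    """Score pipeline predictions against gold coarse labels (and, when
    rankings plus gold evidence maps are given, retrieval quality).

    Instance-id mismatches raise with an explicit diff listing.
    """
    if not predictions:
        raise ValueError("empty prediction set")
    gold_ids = {inst.instance_id for inst in gold_instances}
    pred_ids = set(predictions)
    if gold_ids != pred_ids:
        missing = sorted(gold_ids - pred_ids)[:10]
        extra = sorted(pred_ids - gold_ids)[:10]
        raise ValueError(
            f"instance id mismatch: missing from predictions {missing}, "
            f"unexpected {extra}"
        )
    order = [inst.instance_id for inst in gold_instances]
    gold = [inst.coarse_label.value for inst in gold_instances]
    pred = [predictions[iid].label.value for iid in order]
    report = prf_report(gold, pred, [lab.value for lab in CoarseLabel])
    retrieval = None
    if rankings is not None and retrieval_gold is not None:
        retrieval = retrieval_report(list(rankings.values()), retrieval_gold)
    return report, retrieval
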