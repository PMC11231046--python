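"""Evaluation: classification P/R/F1, retrieval recall@k and MRR,
inter-annotator agreement (Cohen's kappa), and McNemar system comparison.

Conventions
-----------
* Per-class precision/recall/F1 are one-vs-rest; micro averages pool the
  counts (equal to accuracy for single-label full-coverage predictions)
  and macro averages are unweighted means over classes.
* recall@k is the fraction of gold evidence sentences among the top k
  retrieved; MRR is the mean reciprocal rank of the first gold sentence,
  with ranks beyond the cutoff (default 20) contributing 0.  Instances
  with empty gold evidence are excluded from both averages and flagged.
* Cohen's kappa uses the closed form (p_o - p_e) / (1 - p_e) with p_e from
  the marginals; p_e = 1 (both raters constant and identical) is undefined
  and reported as NaN with a flag.
* McNemar compares two systems on their discordant pairs: exact two-sided
  binomial when b + c < 25, continuity-corrected chi-square otherwise.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

from scipy import stats as _scipy_stats
from sklearn.metrics import precision_recall_fscore_support

from .evidence_retrieval import RankedEvidence

__all__ = [
    "ClassMetrics",
    "EvalReport",
    "prf_report",
    "RetrievalReport",
    "recall_at_k",
    "reciprocal_rank",
    "mean_reciprocal_rank",
    "retrieval_report",
    "AgreementReport",
    "cohen_kappa",
    "agreement_report",
    "ComparisonResult",
    "mcnemar",
]


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    per_class: dict[Hashable, ClassMetrics]
    micro_f1: float
    macro_f1: float
    support: dict[Hashable, int]
    flags: list[str] = field(default_factory=list)


def prf_report(
    gold: Sequence[Hashable],
    pred: Sequence[Hashable],
    classes: Sequence[Hashable],
) -> EvalReport:
    """Per-class and aggregate precision/recall/F1.

    Zero-division cases (a class never predicted or never present) yield 0
    for the affected metric and add a flag; macro averaging still includes
    every listed class.
    """
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} pred")
    bad = {lab for lab in itertools.chain(gold, pred) if lab not in set(classes)}
    if bad:
        raise ValueError(f"labels outside class list: {sorted(map(str, bad))}")
    classes = list(classes)
    p, r, f1, support = precision_recall_fscore_support(
        gold, pred, labels=classes, zero_division=0, average=None
    )
    per_class = {
        lab: ClassMetrics(float(pi), float(ri), float(fi))
        for lab, pi, ri, fi in zip(classes, p, r, f1)
    }
    micro = precision_recall_fscore_support(
        gold, pred, labels=classes, zero_division=0, average="micro"
    )[2]
    macro = sum(m.f1 for m in per_class.values()) / len(classes)
    flags = []
    pred_counts = Counter(pred)
    gold_counts = Counter(gold)
    for lab in classes:
        if pred_counts[lab] == 0 or gold_counts[lab] == 0:
            flags.append(f"zero-division for class {lab}: metric set to 0")
    return EvalReport(
        per_class=per_class,
        micro_f1=float(micro),
        macro_f1=float(macro),
        support={lab: int(gold_counts[lab]) for lab in classes},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Retrieval metrics
# ---------------------------------------------------------------------------


def recall_at_k(
    ranking: RankedEvidence, gold_ids: set[str] | Sequence[str], k: int
) -> Optional[float]:
    """|gold in top-k| / |gold|; None (excluded, flagged by callers) when
    the gold set is empty."""
    if k < 1:
        raise ValueError("k must be >= 1")
    gold = set(gold_ids)
    if not gold:
        return None
    top = set(ranking.sentence_ids(k))
    return len(gold & top) / len(gold)


def reciprocal_rank(
    ranking: RankedEvidence, gold_ids: set[str] | Sequence[str], cutoff: int = 20
) -> Optional[float]:
    """1 / rank of the first gold sentence within the cutoff; 0 when no gold
    sentence appears in the top ``cutoff``; None for empty gold."""
    gold = set(gold_ids)
    if not gold:
        return None
    for rank, sid in enumerate(ranking.sentence_ids(cutoff), start=1):
        if sid in gold:
            return 1.0 / rank
    return 0.0


def mean_reciprocal_rank(
    rankings: Sequence[RankedEvidence],
    gold: Mapping[str, set[str] | Sequence[str]],
    cutoff: int = 20,
) -> float:
    """Mean over instances of 1/rank of the first gold sentence within the
    cutoff; instances whose gold set is empty are excluded, and instances
    with no gold sentence in the top ``cutoff`` contribute 0."""
    rrs = [
        rr
        for ranking in rankings
        if (rr := reciprocal_rank(ranking, set(gold.get(ranking.instance_id, ())), cutoff))
        is not None
    ]
    if not rrs:
        return math.nan
    return sum(rrs) / len(rrs)


@dataclass
class RetrievalReport:
    recall_at: dict[int, float]
    mrr: float
    n_evaluated: int
    n_excluded: int
    flags: list[str] = field(default_factory=list)


def retrieval_report(
    rankings: Sequence[RankedEvidence],
    gold: Mapping[str, set[str] | Sequence[str]],
    ks: Sequence[int] = (1, 5, 10, 20),
    mrr_cutoff: int = 20,
) -> RetrievalReport:
    """Average recall@k (k in ``ks``) and MRR over instances.

    ``gold`` maps instance id to its gold evidence sentence ids; instances
    with empty gold are excluded from the averages and counted in
    ``n_excluded``.
    """
    recalls: dict[int, list[float]] = {k: [] for k in ks}
    rrs: list[float] = []
    excluded = 0
    for ranking in rankings:
        gold_ids = set(gold.get(ranking.instance_id, ()))
        if not gold_ids:
            excluded += 1
            continue
        for k in ks:
            recalls[k].append(recall_at_k(ranking, gold_ids, k))
        rrs.append(reciprocal_rank(ranking, gold_ids, mrr_cutoff))
    flags = []
    if excluded:
        flags.append(f"{excluded} instances with empty gold excluded from averages")
    if not rrs:
        flags.append("no instances with gold evidence: metrics undefined")
        return RetrievalReport({k: math.nan for k in ks}, math.nan, 0, excluded, flags)
    return RetrievalReport(
        recall_at={k: sum(v) / len(v) for k, v in recalls.items()},
        mrr=sum(rrs) / len(rrs),
        n_evaluated=len(rrs),
        n_excluded=excluded,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------


def cohen_kappa(
    labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]
) -> float:
    """Chance-corrected agreement between two categorical labelings.

    Returns NaN when expected agreement p_e is 1 (both raters constant and
    identical), where kappa is undefined.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    if not labels_a:
        raise ValueError("empty label sequences")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(ca[lab] * cb.get(lab, 0) for lab in ca) / (n * n)
    if p_e >= 1.0 - 1e-12:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AgreementReport:
    pairwise_kappas: dict[tuple[tuple[str, str], str], float]
    average: dict[str, float]  # per task, over defined pairs
    flags: list[str] = field(default_factory=list)


def agreement_report(
    per_task: Mapping[str, Mapping[str, Sequence[Hashable]]],
) -> AgreementReport:
    """Average pairwise Cohen's kappa per task.

    ``per_task`` maps a task name to {annotator -> label sequence}; all
    annotators of one task must label the same items in the same order
    (for context/evidence tasks, use per-sentence binary membership vectors
    over the agreed sentence universe).  Undefined pairs (p_e = 1) are
    skipped from the average and flagged.
    """
    pairwise: dict[tuple[tuple[str, str], str], float] = {}
    average: dict[str, float] = {}
    flags: list[str] = []
    for task, annotators in per_task.items():
        vals: list[float] = []
        for a, b in itertools.combinations(sorted(annotators), 2):
            kappa = cohen_kappa(annotators[a], annotators[b])
            pairwise[((a, b), task)] = kappa
            if math.isnan(kappa):
                flags.append(f"kappa undefined for pair ({a}, {b}) on task {task}")
            else:
                vals.append(kappa)
        average[task] = sum(vals) / len(vals) if vals else math.nan
    return AgreementReport(pairwise, average, flags)


# ---------------------------------------------------------------------------
# System comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    discordant_counts: tuple[int, int]  # (b, c)
    statistic: float
    p_value: float
    method: str  # "exact_binomial" | "chi2_cc"
    flags: list[str] = field(default_factory=list)


def mcnemar(
    gold: Sequence[Hashable],
    pred_a: Sequence[Hashable],
    pred_b: Sequence[Hashable],
    exact_threshold: int = 25,
) -> ComparisonResult:
    """McNemar's test on the discordant pairs of two systems.

    b = instances system A got right and B wrong; c = the reverse.  The
    exact two-sided binomial test is used when b + c < ``exact_threshold``,
    the continuity-corrected chi-square otherwise.  b + c = 0 yields
    p = 1.0 with a flag.
    """
    if not (len(gold) == len(pred_a) == len(pred_b)):
        raise ValueError("gold/pred_a/pred_b must have equal length")
    b = sum(g == a and g != p for g, a, p in zip(gold, pred_a, pred_b))
    c = sum(g != a and g == p for g, a, p in zip(gold, pred_a, pred_b))
    n = b + c
    if n == 0:
        return ComparisonResult(
            (0, 0), 0.0, 1.0, "exact_binomial", ["no discordant pairs"]
        )
    if n < exact_threshold:
        p = float(_scipy_stats.binomtest(b, n, 0.5).pvalue)
        return ComparisonResult((b, c), float(min(b, c)), p, "exact_binomial")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(_scipy_stats.chi2.sf(stat, df=1))
    return ComparisonResult((b, c), stat, p, "chi2_cc")
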