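"""Metrics: P/R/F1, recall@k, MRR, Cohen's kappa, McNemar."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citecheck.evaluation import (
    agreement_report,
    cohen_kappa,
    mcnemar,
    mean_reciprocal_rank,
    prf_report,
    recall_at_k,
    reciprocal_rank,
    retrieval_report,
)
from citecheck.evidence_retrieval import RankedEvidence


def ranked(ids, instance_id="i"):
    return RankedEvidence(
        instance_id, [(sid, float(len(ids) - k)) for k, sid in enumerate(ids)], "bm25"
    )


class TestPrf:
    def test_perfect_prediction(self):
        rep = prf_report(["a", "b", "c", "a"], ["a", "b", "c", "a"], ["a", "b", "c"])
        assert rep.micro_f1 == 1.0 and rep.macro_f1 == 1.0
        assert all(m.f1 == 1.0 for m in rep.per_class.values())

    def test_confusion_matrix_against_count_oracle(self):
        """3-class confusion matrix [[5,1,0],[2,3,1],[0,0,8]] expanded into
        label sequences; expectations derived by hand from the counts."""
        matrix = [[5, 1, 0], [2, 3, 1], [0, 0, 8]]
        classes = ["x", "y", "z"]
        gold, pred = [], []
        for i, row in enumerate(matrix):
            for j, count in enumerate(row):
                gold += [classes[i]] * count
                pred += [classes[j]] * count
        rep = prf_report(gold, pred, classes)
        # x: tp=5, fp=2, fn=1; y: tp=3, fp=1, fn=3; z: tp=8, fp=1, fn=0
        px, rx = 5 / 7, 5 / 6
        py, ry = 3 / 4, 3 / 6
        pz, rz = 8 / 9, 1.0
        assert rep.per_class["x"].f1 == pytest.approx(2 * px * rx / (px + rx))
        assert rep.per_class["y"].f1 == pytest.approx(2 * py * ry / (py + ry))
        assert rep.per_class["z"].f1 == pytest.approx(2 * pz * rz / (pz + rz))
        assert rep.micro_f1 == pytest.approx(16 / 20)  # pooled accuracy
        assert rep.macro_f1 == pytest.approx(
            sum(rep.per_class[c].f1 for c in classes) / 3
        )

    def test_absent_class_scores_zero_with_flag(self):
        rep = prf_report(["a", "a"], ["a", "a"], ["a", "b"])
        assert rep.per_class["b"].f1 == 0.0
        assert rep.flags
        assert rep.macro_f1 == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            prf_report(["a"], ["a", "b"], ["a", "b"])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.sampled_from("abc"), min_size=1, max_size=60),
        st.randoms(use_true_random=False),
    )
    def test_micro_f1_equals_accuracy(self, gold, rnd):
        pred = [rnd.choice("abc") for _ in gold]
        rep = prf_report(gold, pred, ["a", "b", "c"])
        accuracy = sum(g == p for g, p in zip(gold, pred)) / len(gold)
        assert rep.micro_f1 == pytest.approx(accuracy)


class TestRetrievalMetrics:
    def test_recall_examples(self):
        r = ranked(["s1", "s3", "s5", "s7", "s9"])
        assert recall_at_k(r, {"s3"}, 1) == 0.0
        assert recall_at_k(r, {"s3"}, 5) == 1.0
        assert recall_at_k(r, {"s3", "s100"}, 5) == 0.5

    def test_empty_gold_excluded(self):
        assert recall_at_k(ranked(["s1"]), set(), 5) is None
        report = retrieval_report([ranked(["s1"], "i1")], {"i1": []})
        assert report.n_evaluated == 0 and report.n_excluded == 1
        assert math.isnan(report.mrr)

    def test_mrr_examples(self):
        assert reciprocal_rank(ranked(["s1", "s3"]), {"s3"}) == 0.5
        deep = ranked([f"s{i}" for i in range(30)])
        assert reciprocal_rank(deep, {"s25"}, cutoff=20) == 0.0

    def test_recall_at_full_document_is_one(self):
        ids = [f"s{i}" for i in range(12)]
        assert recall_at_k(ranked(ids), set(ids[3:7]), k=12) == 1.0

    def test_batch_metrics_match_bruteforce_scan(self):
        """100 random instances vs direct set/rank computation."""
        rng = random.Random(31)
        rankings, gold = [], {}
        for i in range(100):
            ids = [f"s{j}" for j in range(rng.randint(5, 40))]
            rng.shuffle(ids)
            rankings.append(ranked(ids, f"i{i}"))
            gold[f"i{i}"] = set(rng.sample(ids, rng.randint(1, 4)))
        report = retrieval_report(rankings, gold, ks=(1, 5, 10, 20))
        for k in (1, 5, 10, 20):
            expected = [
                len(gold[r.instance_id] & set(r.sentence_ids(k)))
                / len(gold[r.instance_id])
                for r in rankings
            ]
            assert report.recall_at[k] == pytest.approx(sum(expected) / len(expected))
        rrs = []
        for r in rankings:
            rr = 0.0
            for pos, sid in enumerate(r.sentence_ids(20), start=1):
                if sid in gold[r.instance_id]:
                    rr = 1.0 / pos
                    break
            rrs.append(rr)
        assert report.mrr == pytest.approx(sum(rrs) / len(rrs))
        assert report.mrr == pytest.approx(mean_reciprocal_rank(rankings, gold))

    def test_recall_non_decreasing_in_k(self):
        rng = random.Random(17)
        for _ in range(20):
            ids = [f"s{j}" for j in range(rng.randint(5, 30))]
            rng.shuffle(ids)
            r = ranked(ids)
            gold = set(rng.sample(ids, rng.randint(1, 5)))
            values = [recall_at_k(r, gold, k) for k in (1, 5, 10, 20)]
            assert values == sorted(values)


class TestCohenKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"]) == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # table a=20, b=5, c=5, d=20: p_o = 0.8, p_e = 0.5, kappa = 0.6
        x = [1] * 25 + [0] * 25
        y = [1] * 20 + [0] * 5 + [1] * 5 + [0] * 20
        assert cohen_kappa(x, y) == pytest.approx((0.8 - 0.5) / 0.5)

    def test_3x3_closed_form(self):
        # constructed marginals: hand-evaluate p_o and p_e directly
        x = ["a"] * 4 + ["b"] * 3 + ["c"] * 3
        y = ["a", "a", "b", "c", "b", "b", "a", "c", "c", "a"]
        n = len(x)
        p_o = sum(i == j for i, j in zip(x, y)) / n
        from collections import Counter

        cx, cy = Counter(x), Counter(y)
        p_e = sum(cx[k] * cy[k] for k in cx) / n**2
        assert cohen_kappa(x, y) == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_constant_annotator(self):
        # one rater constant, the other not: closed form gives kappa = 0
        x = ["a"] * 10
        y = ["a"] * 6 + ["b"] * 4
        assert cohen_kappa(x, y) == pytest.approx(0.0)
        # both constant and identical: p_e = 1, undefined
        assert math.isnan(cohen_kappa(["a"] * 5, ["a"] * 5))

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = random.Random(23)
        for _ in range(30):
            n = rng.randint(5, 50)
            x = [rng.choice("abc") for _ in range(n)]
            y = [rng.choice("abc") for _ in range(n)]
            if len(set(x)) == 1 and x == y:
                continue
            assert cohen_kappa(x, y) == pytest.approx(
                cohen_kappa_score(x, y), abs=1e-12
            )

    def test_invariant_under_category_relabeling(self):
        rng = random.Random(29)
        x = [rng.choice("abc") for _ in range(40)]
        y = [rng.choice("abc") for _ in range(40)]
        base = cohen_kappa(x, y)
        for perm in itertools.permutations("abc"):
            mapping = dict(zip("abc", perm))
            assert cohen_kappa(
                [mapping[v] for v in x], [mapping[v] for v in y]
            ) == pytest.approx(base)

    def test_agreement_report_averages_pairs(self):
        per_task = {
            "accuracy": {
                "ann1": ["a", "b", "a", "a"],
                "ann2": ["a", "b", "b", "a"],
                "ann3": ["b", "b", "a", "a"],
            }
        }
        report = agreement_report(per_task)
        pairs = [(("ann1", "ann2"), "accuracy"), (("ann1", "ann3"), "accuracy"),
                 (("ann2", "ann3"), "accuracy")]
        assert set(report.pairwise_kappas) == set(pairs)
        vals = [report.pairwise_kappas[p] for p in pairs]
        assert report.average["accuracy"] == pytest.approx(sum(vals) / 3)
        assert all(-1.0 <= v <= 1.0 for v in vals)


class TestMcnemar:
    @staticmethod
    def _make_preds(b, c, n_extra=10):
        """Label sequences realizing discordant counts (b, c)."""
        gold, pa, pb = [], [], []
        for _ in range(b):  # A right, B wrong
            gold.append("x"); pa.append("x"); pb.append("y")
        for _ in range(c):  # A wrong, B right
            gold.append("x"); pa.append("y"); pb.append("x")
        for _ in range(n_extra):  # concordant
            gold.append("x"); pa.append("x"); pb.append("x")
        return gold, pa, pb

    @staticmethod
    def binomial_two_sided(b, c):
        """Direct binomial summation oracle at p = 1/2."""
        n = b + c
        probs = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
        observed = probs[b]
        return min(1.0, sum(p for p in probs if p <= observed * (1 + 1e-12)))

    def test_symmetric_counts_give_p_one(self):
        gold, pa, pb = self._make_preds(4, 4)
        res = mcnemar(gold, pa, pb)
        assert res.discordant_counts == (4, 4)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "exact_binomial"

    def test_exact_p_matches_binomial_sum(self):
        gold, pa, pb = self._make_preds(10, 2)
        res = mcnemar(gold, pa, pb)
        assert res.p_value == pytest.approx(self.binomial_two_sided(10, 2), abs=1e-12)

    def test_all_small_tables_match_oracle(self):
        """Every (b, c) with b + c <= 20 against the summation oracle."""
        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                gold, pa, pb = self._make_preds(b, c)
                res = mcnemar(gold, pa, pb)
                assert res.method == "exact_binomial"
                assert res.p_value == pytest.approx(
                    self.binomial_two_sided(b, c), abs=1e-12
                ), (b, c)

    def test_swapping_systems_preserves_p(self):
        gold, pa, pb = self._make_preds(7, 3)
        assert mcnemar(gold, pa, pb).p_value == pytest.approx(
            mcnemar(gold, pb, pa).p_value
        )

    def test_no_discordant_pairs(self):
        gold, pa, pb = self._make_preds(0, 0)
        res = mcnemar(gold, pa, pb)
        assert res.p_value == 1.0 and res.flags

    def test_large_table_uses_corrected_chi2(self):
        gold, pa, pb = self._make_preds(30, 12)
        res = mcnemar(gold, pa, pb)
        assert res.method == "chi2_cc"
        # cross-check against statsmodels' continuity-corrected version
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[len(gold) - 42, 30], [12, 0]]
        sm = sm_mcnemar(table, exact=False, correction=True)
        assert res.statistic == pytest.approx(sm.statistic)
        assert res.p_value == pytest.approx(sm.pvalue)
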