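import numpy as np
import pytest

from kgfuse.ensemble import (
    aggregate_avg,
    aggregate_sum,
    position_ensemble,
    product_of_experts,
    select_top_models,
)
from kgfuse.errors import ConfigError, DataError
from kgfuse.evaluate import EvalReport
from kgfuse.normalize import rank_normalize
from kgfuse.scores import ScoreTable, TopKScores
import pandas as pd


def topk(model_id, entries, method="minmax", percentile=99.0):
    """entries: list of (drug, disease, normalized) best-first."""
    frame = pd.DataFrame(
        {
            "drug": [e[0] for e in entries],
            "disease": [e[1] for e in entries],
            "raw_score": [len(entries) - i for i in range(len(entries))],
            "normalized": [e[2] for e in entries],
            "rank": np.arange(1, len(entries) + 1),
        }
    )
    return TopKScores(model_id, percentile, method, frame)


class TestSum:
    def test_single_table_identity(self):
        t = topk("m0", [("a", "x", 1.0), ("b", "y", 0.4), ("c", "z", 0.1)])
        r = aggregate_sum([t])
        assert r.ranked_pairs() == [("a", "x"), ("b", "y"), ("c", "z")]

    def test_frequency_weighting_hand_example(self):
        # A scored {0.9, 0.2} by two models sums to 1.1 and beats B's single 1.0
        t1 = topk("m0", [("A", "x", 0.9), ("B", "y", 1.0)])
        t2 = topk("m1", [("A", "x", 0.2)])
        r = aggregate_sum([t1, t2])
        assert r.ranked_pairs()[0] == ("A", "x")
        assert r.frame.iloc[0]["score"] == pytest.approx(1.1)
        assert r.frame.iloc[1]["score"] == pytest.approx(1.0)
        assert int(r.frame.iloc[0]["n_models"]) == 2

    def test_pair_in_no_table_absent(self):
        t1 = topk("m0", [("A", "x", 0.9)])
        r = aggregate_sum([t1])
        assert ("B", "y") not in set(r.ranked_pairs())

    def test_mixed_methods_rejected(self):
        t1 = topk("m0", [("A", "x", 1.0)], method="minmax")
        t2 = topk("m1", [("A", "x", 1.0)], method="rank")
        with pytest.raises(ConfigError):
            aggregate_sum([t1, t2])

    def test_mixed_percentiles_rejected(self):
        t1 = topk("m0", [("A", "x", 1.0)], percentile=99.0)
        t2 = topk("m1", [("A", "x", 1.0)], percentile=95.0)
        with pytest.raises(ConfigError):
            aggregate_sum([t1, t2])

    def test_monotonicity_under_supporting_member(self, rng):
        """Adding a member that scores only pair t cannot lower t's rank."""
        base = [topk(f"m{i}",
                     [(f"d{j}", "z", float(v)) for j, v in
                      enumerate(rng.random(8).round(3))])
                for i in range(3)]
        target = ("d3", "z")
        before = aggregate_sum(base).ranked_pairs().index(target)
        extra = topk("m9", [(target[0], target[1], 0.7)])
        after = aggregate_sum(base + [extra]).ranked_pairs().index(target)
        assert after <= before


class TestAvg:
    def test_hand_example_two_of_ten_models(self):
        tables = [topk("m0", [("A", "x", 0.9)]), topk("m1", [("A", "x", 0.2)])]
        tables += [topk(f"m{i}", [(f"q{i}", "w", 0.01)]) for i in range(2, 10)]
        rz = aggregate_avg(tables, "avg_zero")
        rp = aggregate_avg(tables, "avg_present")
        a_zero = rz.frame.set_index(["drug", "disease"]).loc[("A", "x"), "score"]
        a_pres = rp.frame.set_index(["drug", "disease"]).loc[("A", "x"), "score"]
        assert a_zero == pytest.approx(0.11)
        assert a_pres == pytest.approx(0.55)

    def test_avg_zero_order_equals_sum_order(self, rng):
        tables = []
        for i in range(4):
            n = rng.integers(3, 10)
            entries = [(f"d{rng.integers(12)}", f"z{rng.integers(4)}",
                        float(rng.random())) for _ in range(n)]
            seen = set()
            uniq = [e for e in entries if not (
                (e[0], e[1]) in seen or seen.add((e[0], e[1])))]
            tables.append(topk(f"m{i}", uniq))
        assert (aggregate_avg(tables, "avg_zero").ranked_pairs()
                == aggregate_sum(tables).ranked_pairs())

    def test_single_model_identity(self):
        t = topk("m0", [("a", "x", 0.8), ("b", "y", 0.3)])
        for mode in ("avg_zero", "avg_present"):
            assert aggregate_avg([t], mode).ranked_pairs() == [("a", "x"),
                                                               ("b", "y")]


class TestPoE:
    def test_single_model_preserves_raw_order(self, rng):
        scores = rng.normal(size=20)
        pairs = [(f"d{i}", "z") for i in range(20)]
        t = ScoreTable.from_pairs("m0", pairs, scores)
        r = product_of_experts([t])
        expected = [pairs[i] for i in np.argsort(-scores)]
        assert r.ranked_pairs() == expected

    def test_two_models_match_brute_force_product(self):
        pairs = [("a", "x"), ("b", "y"), ("c", "z")]
        s1, s2 = [1.0, 0.2, -0.5], [0.0, 2.0, 1.0]
        t1 = ScoreTable.from_pairs("m0", pairs, s1)
        t2 = ScoreTable.from_pairs("m1", pairs, s2)
        r = product_of_experts([t1, t2])
        p1 = np.exp(s1) / np.exp(s1).sum()
        p2 = np.exp(s2) / np.exp(s2).sum()
        brute = [pairs[i] for i in np.argsort(-(p1 * p2))]
        assert r.ranked_pairs() == brute

    def test_veto_by_one_expert(self):
        pairs = [("a", "x"), ("b", "y"), ("c", "z")]
        vetoer = ScoreTable.from_pairs("m0", pairs, [1.0, 1.0, -3.0])
        indifferent = ScoreTable.from_pairs("m1", pairs, [0.5, 0.5, 0.5])
        r = product_of_experts([vetoer, indifferent])
        assert r.ranked_pairs()[-1] == ("c", "z")

    def test_space_mismatch_rejected(self):
        t1 = ScoreTable.from_pairs("m0", [("a", "x"), ("b", "y")], [1, 2])
        t2 = ScoreTable.from_pairs("m1", [("a", "x"), ("c", "z")], [1, 2])
        with pytest.raises(ConfigError, match="mismatch"):
            product_of_experts([t1, t2])


class TestPosition:
    def test_requires_rank_method(self):
        t = topk("m0", [("a", "x", 1.0)], method="minmax")
        with pytest.raises(ConfigError):
            position_ensemble([t])

    def test_k5_tradeoff_hand_example(self):
        # rank norm with k=5: values 1.0, 0.75, 0.5, 0.25, 0.0
        def ranked(model_id, order):
            vals = [1.0, 0.75, 0.5, 0.25, 0.0]
            return topk(model_id, [(d, z, v) for (d, z), v in zip(order, vals)],
                        method="rank")

        others = [(f"f{i}", "w") for i in range(3)]
        t1 = ranked("m0", [("A", "x"), ("B", "y")] + others)
        t2 = ranked("m1", [("B", "y"), *others, ("A", "x")])
        r = position_ensemble([t1, t2])
        scores = r.frame.set_index(["drug", "disease"])["score"]
        assert scores.loc[("A", "x")] == pytest.approx(1.0)  # 1.0 + 0.0
        assert scores.loc[("B", "y")] == pytest.approx(1.75)  # 0.75 + 1.0
        assert r.ranked_pairs().index(("B", "y")) < r.ranked_pairs().index(("A", "x"))

    def test_consensus_identity(self, rng):
        scores = {(f"d{i}", "z"): float(10 - i) for i in range(6)}
        tabs = []
        for i in range(3):
            t = ScoreTable.from_pairs(f"m{i}", list(scores), list(scores.values()))
            tabs.append(rank_normalize(t))
        r = position_ensemble(tabs)
        assert r.ranked_pairs() == [(f"d{i}", "z") for i in range(6)]


class TestSelectTop:
    @staticmethod
    def report(model, p100):
        return EvalReport(model, (100,), {100: p100}, {100: int(p100 * 100)})

    def test_matches_sort_oracle(self, rng):
        precisions = rng.permutation(10) / 10
        reports = {f"m{i}": self.report(f"m{i}", p)
                   for i, p in enumerate(precisions)}
        got = select_top_models(reports, 5)
        brute = sorted(reports, key=lambda m: -reports[m].precision_at_k[100])[:5]
        assert got == brute

    def test_all_returned_when_n_equals_count(self):
        reports = {f"m{i}": self.report(f"m{i}", i / 10) for i in range(5)}
        assert select_top_models(reports, 5) == ["m4", "m3", "m2", "m1", "m0"]

    def test_tie_broken_lexicographically(self):
        reports = {m: self.report(m, 0.3) for m in ("mb", "ma", "mc")}
        assert select_top_models(reports, 2) == ["ma", "mb"]

    def test_missing_p100_rejected(self):
        reports = {"ma": self.report("ma", 0.3),
                   "mb": EvalReport("mb", (10,), {10: 0.5}, {10: 5})}
        with pytest.raises(DataError, match="mb"):
            select_top_models(reports, 1)


def test_tie_break_is_stable_across_runs():
    """Equal ensemble scores resolve by (n_models desc, drug, disease)."""
    t1 = topk("m0", [("b", "y", 0.5), ("a", "x", 0.5)])
    orders = {tuple(aggregate_sum([t1]).ranked_pairs()) for _ in range(5)}
    assert orders == {(("a", "x"), ("b", "y"))}
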