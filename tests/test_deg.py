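"""Differential expression, overlap partitions, enrichment, redundancy."""

import math

import numpy as np
import pandas as pd
import pytest

from infantsep.io import ExpressionMatrix, GeneSetCollection
from infantsep.deg import (
    module_expression_summary,
    ora,
    overlap_partition,
    redundancy_filter,
    wilcoxon_deg,
)


def _expr(arr, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestWilcoxonDEG:
    def test_overlapping_groups_rejected(self, rng):
        e = _expr(rng.normal(size=(5, 10)))
        ids = e.sample_ids
        with pytest.raises(ValueError, match="share"):
            wilcoxon_deg(e, ids[:5], ids[4:])

    def test_antisymmetry(self, rng):
        e = _expr(rng.normal(size=(30, 16)))
        a, b = e.sample_ids[:8], e.sample_ids[8:]
        t1 = wilcoxon_deg(e, a, b)
        t2 = wilcoxon_deg(e, b, a)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-12)

    def test_planted_shift_recovered_exactly(self, rng):
        n_genes, shift_genes = 400, 10
        arr = rng.normal(8, 0.5, size=(n_genes, 40))
        arr[:shift_genes, :20] += 2.0
        e = _expr(arr)
        tab = wilcoxon_deg(e, e.sample_ids[:20], e.sample_ids[20:])
        flagged = set(tab.index[tab.significant])
        assert flagged == {f"g{i}" for i in range(shift_genes)}

    def test_null_calibration_short(self, rng):
        # 10-replicate sanity check; the full 100-replicate calibration runs
        # in the acceptance suite
        rates = []
        for _ in range(10):
            arr = rng.normal(size=(500, 40))
            e = _expr(arr)
            tab = wilcoxon_deg(e, e.sample_ids[:20], e.sample_ids[20:])
            rates.append((tab["p"] < 0.05).mean())
            assert tab["significant"].sum() == 0
        assert np.mean(rates) == pytest.approx(0.05, abs=0.015)

    def test_padjust_never_below_p(self, rng):
        e = _expr(rng.normal(size=(100, 12)))
        tab = wilcoxon_deg(e, e.sample_ids[:6], e.sample_ids[6:])
        assert (tab["p_adjust"] >= tab["p"] - 1e-15).all()


class TestOverlapPartition:
    def test_identical_lists_all_shared(self):
        out = overlap_partition({"a": ["x", "y"], "b": ["x", "y"]})
        assert out[frozenset({"a", "b"})] == 2
        assert out[frozenset({"a"})] == 0

    def test_disjoint_lists(self):
        out = overlap_partition({"a": ["x"], "b": ["y"], "c": ["z"]})
        assert out[frozenset({"a"})] == 1
        assert out[frozenset({"a", "b", "c"})] == 0

    def test_matches_set_algebra_oracle(self, rng):
        pool = [f"g{i}" for i in range(30)]
        lists = {
            k: list(rng.choice(pool, size=12, replace=False)) for k in ("A", "B", "C")
        }
        out = overlap_partition(lists)
        sets = {k: set(v) for k, v in lists.items()}
        for pattern, count in out.items():
            inside = set.intersection(*(sets[k] for k in pattern))
            outside = set().union(*(sets[k] for k in sets if k not in pattern))
            assert count == len(inside - outside)
        assert sum(out.values()) == len(set().union(*sets.values()))

    def test_more_than_three_rejected(self):
        with pytest.raises(ValueError):
            overlap_partition({k: [] for k in "abcd"})


class TestORA:
    def test_full_set_recovery_with_exact_tail(self):
        universe = [f"g{i}" for i in range(1000)]
        target = universe[:10]
        sets = GeneSetCollection(
            {"T": ("target", list(target)), "U": ("other", universe[100:140])}
        )
        tab = ora(list(target), sets, universe)
        assert tab.index[0] == "T"
        # closed-form hypergeometric tail: all 10 of 10 drawn
        N, m, n, k = 1000, 10, 10, 10
        expected = sum(
            math.comb(m, i) * math.comb(N - m, n - i) for i in range(k, min(m, n) + 1)
        ) / math.comb(N, n)
        assert tab.loc["T", "p"] == pytest.approx(expected, rel=1e-12)
        assert tab.loc["T", "significant"]

    def test_exact_enumeration_small_universe(self, rng):
        universe = [f"g{i}" for i in range(40)]
        members = list(rng.choice(universe, size=12, replace=False))
        query = list(rng.choice(universe, size=9, replace=False))
        sets = GeneSetCollection({"S": ("s", members)})
        tab = ora(query, sets, universe)
        N, m, n = 40, 12, 9
        k = len(set(query) & set(members))
        expected = sum(
            math.comb(m, i) * math.comb(N - m, n - i) for i in range(k, min(m, n) + 1)
        ) / math.comb(N, n)
        assert tab.loc["S", "p"] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_and_small_sets_skipped(self):
        universe = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection(
            {"OUT": ("outside", ["zz1", "zz2", "zz3"]), "TINY": ("tiny", universe[:2])}
        )
        tab = ora(universe[:5], sets, universe)
        assert len(tab) == 0

    def test_zero_overlap_never_significant(self):
        universe = [f"g{i}" for i in range(100)]
        sets = GeneSetCollection({"S": ("s", universe[50:60])})
        tab = ora(universe[:10], sets, universe)
        assert tab.loc["S", "overlap_k"] == 0
        assert tab.loc["S", "p"] == pytest.approx(1.0, abs=1e-9) or tab.loc["S", "p"] > 0.3
        assert not tab.loc["S", "significant"]


class TestRedundancyFilter:
    def _table(self, term_ids, ps):
        return pd.DataFrame(
            {"p": ps, "p_adjust": ps}, index=pd.Index(term_ids, name="term_id")
        )

    def test_disjoint_terms_all_kept(self):
        universe = [f"g{i}" for i in range(30)]
        sets = GeneSetCollection(
            {"A": ("a", universe[:5]), "B": ("b", universe[5:10]), "C": ("c", universe[10:15])}
        )
        tab = self._table(["A", "B", "C"], [0.001, 0.002, 0.003])
        kept = redundancy_filter(tab, sets, universe)
        assert list(kept.index) == ["A", "B", "C"]

    def test_duplicate_membership_keeps_better_p(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"A": ("a", universe[:6]), "B": ("b", universe[:6])})
        tab = self._table(["B", "A"], [0.01, 0.001])
        kept = redundancy_filter(tab, sets, universe)
        assert list(kept.index) == ["A"]

    def test_nested_sets_hand_jaccard(self):
        universe = [f"g{i}" for i in range(20)]
        big = universe[:10]
        small = universe[:5]  # Jaccard 5/10 = 0.5 > 0.4
        sets = GeneSetCollection({"BIG": ("b", big), "SMALL": ("s", small)})
        tab = self._table(["BIG", "SMALL"], [0.001, 0.01])
        kept = redundancy_filter(tab, sets, universe, threshold=0.4)
        assert list(kept.index) == ["BIG"]
        kept2 = redundancy_filter(tab, sets, universe, threshold=0.6)
        assert list(kept2.index) == ["BIG", "SMALL"]

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            redundancy_filter(self._table(["A"], [0.1]), GeneSetCollection({}), [], 1.5)


class TestModuleSummary:
    def test_single_group_rejected(self, rng):
        e = _expr(rng.normal(size=(10, 6)))
        with pytest.raises(ValueError):
            module_expression_summary(e, e.gene_ids[:3], {"only": e.sample_ids})

    def test_absent_module_rejected(self, rng):
        e = _expr(rng.normal(size=(4, 6)))
        with pytest.raises(ValueError):
            module_expression_summary(
                e, ["nope"], {"a": e.sample_ids[:3], "b": e.sample_ids[3:]}
            )

    def test_null_calibration(self, rng):
        hits = 0
        for _ in range(100):
            e = _expr(rng.normal(size=(10, 30)))
            out = module_expression_summary(
                e,
                e.gene_ids[:5],
                {"a": e.sample_ids[:10], "b": e.sample_ids[10:20], "c": e.sample_ids[20:]},
            )
            if any(p < 0.05 for p in out["dunn_p"].values()):
                hits += 1
        assert hits <= 10

    def test_planted_severity_ordering(self, conormalized):
        cohort, truth, _, post = conormalized
        module = list(truth.modules["hemostasis_up"].genes)
        groups = {
            "control": cohort.group_ids("HealthyControl"),
            "bacteremia": cohort.group_ids("Bacteremia"),
            "shock": cohort.group_ids("SepticShock"),
        }
        out = module_expression_summary(post.expr, module, groups)
        means = out["per_group"]["mean"]
        assert means["control"] < means["bacteremia"] < means["shock"]
        assert out["kruskal_p"] < 1e-6
        assert out["dunn_p"][("control", "shock")] < 1e-6
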