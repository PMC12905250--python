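"""Newick parsing, DTL reconciliation, and the co-cladogenesis test."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from symfid.cophylogeny import (
    AssociationError,
    DtlCosts,
    DuplicateLabelError,
    NewickError,
    PolytomyError,
    cocladogenesis_test,
    dtl_min_cost,
    parse_newick,
    randomize_tip_association,
    write_newick,
)
from symfid.synthetic import TreePairTruth, simulate_tree_pair

from _oracles import dtl_min_cost_exhaustive

UNIT = DtlCosts(1, 1, 1)


class TestParseNewick:
    @pytest.mark.parametrize(
        "text, n_tips, n_internal",
        [("(A,B);", 2, 1), ("((A,B),C);", 3, 2), ("A;", 1, 0)],
    )
    def test_valid_shapes(self, text, n_tips, n_internal):
        tree = parse_newick(text)
        assert tree.n_tips == n_tips
        internals = sum(1 for n in tree.postorder() if not n.is_leaf())
        assert internals == n_internal

    def test_tip_order_preserved(self):
        assert parse_newick("((B,A),(D,C));").tip_labels == ["B", "A", "D", "C"]

    def test_polytomy_rejected(self):
        with pytest.raises(PolytomyError):
            parse_newick("(A,B,C);")

    @pytest.mark.parametrize("text", ["((A,B);", "(A,B));", "(A,B)", "(A,(B,C);"])
    def test_malformed_rejected(self, text):
        with pytest.raises(NewickError):
            parse_newick(text)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DuplicateLabelError):
            parse_newick("((A,B),A);")


def _rf_distance(newick1: str, newick2: str) -> int:
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestWriteNewick:
    def test_round_trip_small(self):
        assert write_newick(parse_newick("(A,B);")) == "(A,B);"

    def test_round_trip_random_yule_rf_zero(self):
        host, _, _ = simulate_tree_pair(TreePairTruth(n_tips=20, seed=5))
        text = write_newick(host)
        again = write_newick(parse_newick(text))
        assert _rf_distance(text, again) == 0

    @given(st.integers(2, 15), st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_round_trip_idempotent_on_random_trees(self, n_tips, seed):
        host, _, _ = simulate_tree_pair(TreePairTruth(n_tips=n_tips, seed=seed))
        once = write_newick(host)
        assert write_newick(parse_newick(once)) == once

    def test_branch_lengths_preserved(self):
        tree = parse_newick("(A:0.123456,B:2.5);")
        reparsed = parse_newick(write_newick(tree))
        lengths = sorted(
            n.length for n in reparsed.postorder() if n.length is not None
        )
        assert lengths == pytest.approx([0.123456, 2.5], abs=1e-6)


class TestDtlMinCost:
    def test_cospeciation_at_root_costs_zero(self):
        host, sym = parse_newick("(A,B);"), parse_newick("(a,b);")
        assert dtl_min_cost(host, sym, {"a": "A", "b": "B"}, UNIT).min_cost == 0

    def test_single_tip_trees(self):
        assert dtl_min_cost(
            parse_newick("A;"), parse_newick("a;"), {"a": "A"}, UNIT
        ).min_cost == 0

    def test_three_tip_single_transfer(self):
        # one symbiont tip swapped relative to the host: one transfer suffices
        host, sym = parse_newick("((A,B),C);"), parse_newick("((a,c),b);")
        assoc = {"a": "A", "b": "B", "c": "C"}
        assert dtl_min_cost(host, sym, assoc, UNIT).min_cost == 1
        assert dtl_min_cost_exhaustive(host, sym, assoc, UNIT) == 1

    def test_non_bijective_association_rejected(self):
        host, sym = parse_newick("(A,B);"), parse_newick("(a,b);")
        with pytest.raises(AssociationError):
            dtl_min_cost(host, sym, {"a": "A", "b": "A"}, UNIT)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            n = int(rng.integers(2, 6))
            switches = int(rng.integers(0, 3)) if n >= 3 else 0
            host, sym, assoc = simulate_tree_pair(
                TreePairTruth(n_tips=n, n_switch_events=switches, seed=trial)
            )
            costs = DtlCosts(*np.round(rng.uniform(0.2, 2.0, 3), 2))
            if rng.random() < 0.5:
                assoc = randomize_tip_association(assoc, rng)
            dp = dtl_min_cost(host, sym, assoc, costs).min_cost
            oracle = dtl_min_cost_exhaustive(host, sym, assoc, costs)
            assert dp == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_each_event_cost(self):
        host, sym, assoc = simulate_tree_pair(
            TreePairTruth(n_tips=8, n_switch_events=2, seed=3)
        )
        base = dtl_min_cost(host, sym, assoc, UNIT).min_cost
        for bumped in (DtlCosts(2, 1, 1), DtlCosts(1, 2, 1), DtlCosts(1, 1, 2)):
            assert dtl_min_cost(host, sym, assoc, bumped).min_cost >= base


class TestRandomizeTipAssociation:
    def test_single_tip_unchanged(self):
        assert randomize_tip_association({"a": "A"}, 0) == {"a": "A"}

    def test_keys_preserved(self):
        assoc = {f"s{i}": f"H{i}" for i in range(9)}
        out = randomize_tip_association(assoc, 1)
        assert set(out) == set(assoc)
        assert sorted(out.values()) == sorted(assoc.values())

    def test_uniform_over_all_bijections(self):
        """Each of the 6! bijections on 6 tips appears ~1/720 of the time."""
        n, draws = 6, 100_000
        assoc = {f"s{i}": f"H{i}" for i in range(n)}
        rng = np.random.default_rng(2024)
        counts = {}
        for _ in range(draws):
            shuffled = randomize_tip_association(assoc, rng)
            key = tuple(shuffled[f"s{i}"] for i in range(n))
            counts[key] = counts.get(key, 0) + 1
        observed = np.zeros(math.factorial(n))
        observed[: len(counts)] = sorted(counts.values())
        chi2 = ((observed - draws / 720) ** 2 / (draws / 720)).sum()
        p = sps.chi2.sf(chi2, df=719)
        assert p > 0.01


class TestCocladogenesisTest:
    def test_zero_permutations_gives_p_one(self):
        host, sym, assoc = simulate_tree_pair(TreePairTruth(6, 0, seed=0))
        res = cocladogenesis_test(host, sym, assoc, UNIT, n_perm=0, seed=0)
        assert res.p_value == 1.0

    def test_congruent_pair_reaches_minimal_p(self):
        """A perfectly co-diverged 12-tip pair with 100 randomizations hits
        the smallest attainable add-one p, 1/101 ~ 0.0099."""
        host, sym, assoc = simulate_tree_pair(TreePairTruth(12, 0, seed=1))
        res = cocladogenesis_test(host, sym, assoc, UNIT, n_perm=100, seed=1)
        assert res.observed_cost == 0
        assert res.p_value == pytest.approx(1 / 101)

    def test_p_value_bounds_and_formula(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            host, sym, assoc = simulate_tree_pair(TreePairTruth(7, 2, seed=seed))
            assoc = randomize_tip_association(assoc, rng)
            res = cocladogenesis_test(host, sym, assoc, UNIT, n_perm=20, seed=seed)
            assert 1 / 21 <= res.p_value <= 1.0
            n_le = sum(1 for c in res.permuted_costs if c <= res.observed_cost)
            assert res.p_value == (1 + n_le) / (1 + 20)

    def test_null_is_valid_and_conservative(self):
        """With the association itself random, the test must not reject at
        more than its nominal rate.  DTL costs of random bijections are
        heavily tied, so with ties counted as extreme the p-value is
        conservative (it concentrates high, never low)."""
        ps = []
        for seed in range(200):
            host, sym, assoc = simulate_tree_pair(TreePairTruth(12, 0, seed=seed))
            assoc = randomize_tip_association(assoc, np.random.default_rng(seed + 10_000))
            ps.append(
                cocladogenesis_test(host, sym, assoc, UNIT, n_perm=99, seed=seed).p_value
            )
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.05 + 0.02  # nominal rate + MC slack
        assert np.median(ps) >= 0.35  # not concentrated low
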