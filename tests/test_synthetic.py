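"""Ground-truth generators: determinism and recovery of the planted signal."""

import numpy as np
import pandas as pd
import pytest

from symfid.cophylogeny import DtlCosts, dtl_min_cost, write_newick
from symfid.synthetic import (
    GenomePairTruth,
    SurvivalTruth,
    TrajectoryTruth,
    TreePairTruth,
    simulate_competition_trajectories,
    simulate_genome_pair,
    simulate_infection_counts,
    simulate_survival_cohorts,
    simulate_tree_pair,
)

UNIT = DtlCosts(1, 1, 1)


class TestTreePair:
    def test_seed_determinism(self):
        a = simulate_tree_pair(TreePairTruth(10, 2, seed=9))
        b = simulate_tree_pair(TreePairTruth(10, 2, seed=9))
        assert write_newick(a[0]) == write_newick(b[0])
        assert write_newick(a[1]) == write_newick(b[1])
        assert a[2] == b[2]

    def test_no_switches_is_perfectly_congruent(self):
        host, sym, assoc = simulate_tree_pair(TreePairTruth(12, 0, seed=4))
        # identical topology up to relabelling: reconciles for free
        assert dtl_min_cost(host, sym, assoc, UNIT).min_cost == 0

    def test_association_is_bijection(self):
        for seed in range(5):
            host, sym, assoc = simulate_tree_pair(TreePairTruth(9, 3, seed=seed))
            assert sorted(assoc) == sorted(sym.tip_labels)
            assert sorted(assoc.values()) == sorted(host.tip_labels)

    def test_switches_create_bounded_incongruence(self):
        """Each tip SPR move needs at most one transfer plus a few losses to
        reconcile (empirically <= transfer + 3 losses per move), and a
        single move always breaks perfect congruence."""
        for seed in range(50):
            for k in (1, 2, 3):
                host, sym, assoc = simulate_tree_pair(TreePairTruth(12, k, seed=seed))
                cost = dtl_min_cost(host, sym, assoc, UNIT).min_cost
                assert cost <= k * 4
                if k == 1:
                    assert cost > 0

    def test_switches_impossible_on_two_tips(self):
        with pytest.raises(ValueError):
            simulate_tree_pair(TreePairTruth(2, 1, seed=0))


class TestGenomePair:
    def test_zero_divergence_is_identity(self):
        ga, gb, coords = simulate_genome_pair(
            GenomePairTruth(n_genes=10, subs_prob=0.0, n_inversions=0, seed=0)
        )
        assert ga == gb
        assert len(ga) == GenomePairTruth(n_genes=10).genome_len

    def test_seed_determinism(self):
        t = GenomePairTruth(n_genes=12, subs_prob=0.1, n_inversions=2, seed=5)
        a, b = simulate_genome_pair(t), simulate_genome_pair(t)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].equals(b[2])

    def test_substitution_rate_matches_bernoulli_expectation(self):
        p = 0.05
        ga, gb, _ = simulate_genome_pair(
            GenomePairTruth(n_genes=50, subs_prob=p, n_inversions=0, seed=2)
        )
        mismatch = np.mean([x != y for x, y in zip(ga, gb)])
        L = len(ga)
        assert abs(mismatch - p) < 4 * np.sqrt(p * (1 - p) / L)

    def test_inversions_appear_as_strand_breakpoints(self):
        _, _, coords = simulate_genome_pair(
            GenomePairTruth(n_genes=40, subs_prob=0.0, n_inversions=3, seed=7)
        )
        strands = coords[coords.genome == "B"].sort_values("gene_id", key=lambda s: s.str[4:].astype(int))["strand"].tolist()
        runs = sum(
            1 for i, s in enumerate(strands) if s == "-" and (i == 0 or strands[i - 1] == "+")
        )
        assert runs == 3

    def test_unplaceable_inversions_raise(self):
        with pytest.raises(ValueError):
            simulate_genome_pair(GenomePairTruth(n_genes=6, n_inversions=5, seed=0))


class TestCompetitionTrajectories:
    def test_noiseless_is_exact_exponential(self):
        t = TrajectoryTruth(noise_cv=0.0, seed=0)
        table = simulate_competition_trajectories(t)
        for _, row in table.iterrows():
            n0 = t.n0_native if row.strain == "native" else t.n0_nonnative
            m = t.m_native if row.strain == "native" else t.m_nonnative
            assert row.copies == pytest.approx(n0 * np.exp(m * row.day), rel=1e-12)

    def test_noiseless_log_ratio_linear(self):
        t = TrajectoryTruth(m_native=0.5, m_nonnative=0.47, noise_cv=0.0, seed=0)
        table = simulate_competition_trajectories(t)
        wide = table.pivot_table(index=["replicate", "day"], columns="strain", values="copies")
        ratio = np.log(wide["non_native"] / wide["native"])
        days = wide.index.get_level_values("day").to_numpy()
        slope = np.polyfit(days, ratio, 1)[0]
        assert slope == pytest.approx(-0.03, abs=1e-12)

    def test_noise_cv_calibrated(self):
        """Empirical CV of the multiplicative error within 5% of noise_cv."""
        cv = 0.3
        t = TrajectoryTruth(noise_cv=cv, n_reps=5000, days=(1.0,), seed=3)
        table = simulate_competition_trajectories(t)
        native = table[table.strain == "native"]
        eps = native.copies / (t.n0_native * np.exp(t.m_native * 1.0))
        assert len(eps) == 5000
        assert abs(eps.std() / eps.mean() - cv) < 0.05 * cv
        assert abs(eps.mean() - 1.0) < 0.02

    def test_seed_determinism(self):
        t = TrajectoryTruth(seed=11)
        assert simulate_competition_trajectories(t).equals(
            simulate_competition_trajectories(t)
        )


class TestSurvivalCohorts:
    def test_negligible_hazard_censors_everyone(self):
        t = SurvivalTruth(baseline_hazard=1e-12, effect_beta=0.0, seed=0)
        table = simulate_survival_cohorts(t)
        assert (table.event == 0).all()
        assert (table.day == t.censor_day).all()

    def test_zero_effect_equalizes_hazards(self):
        t = SurvivalTruth(effect_beta=0.0)
        hazards = set(t.hazards().values())
        assert len(hazards) == 1

    def test_relatedness_gradient_orders_survivorship(self):
        """With a positive hazard effect, mean survivorship at the censoring
        day increases with relatedness (in expectation over 100 seeds)."""
        groups = (("low", 40.0), ("mid", 70.0), ("high", 100.0))
        frac = {g: [] for g, _ in groups}
        for seed in range(100):
            t = SurvivalTruth(
                group_relatedness=groups, n_per_group=20, effect_beta=3.0, seed=seed
            )
            table = simulate_survival_cohorts(t)
            for g, _ in groups:
                sub = table[table.group == g]
                frac[g].append((sub.event == 0).mean())
        assert np.mean(frac["low"]) < np.mean(frac["mid"]) < np.mean(frac["high"])


class TestInfectionCounts:
    @pytest.mark.parametrize("p, n, expected", [(1.0, 24, 24), (0.0, 19, 0)])
    def test_degenerate_probabilities(self, p, n, expected):
        assert simulate_infection_counts(p, n, seed=0) == expected

    def test_binomial_three_sigma_coverage(self):
        """p=0.5, n=1000: draws fall in 500 +/- 47 for >= 99% of seeds."""
        hits = sum(
            1 for seed in range(200) if abs(simulate_infection_counts(0.5, 1000, seed) - 500) <= 47
        )
        assert hits >= 198
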