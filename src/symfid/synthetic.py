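"""Synthetic data with known ground truth for every analysis stage.

Generates the five kinds of inputs the pipeline consumes:

* co-diverged host/symbiont tree pairs with a controlled number of
  host-switch events (tip subtree-prune-regraft moves on the symbiont tree);
* genome pairs related by a controlled per-site substitution probability and
  a controlled number of segmental inversions, emulating drastically reduced
  (~0.25 Mb scale, here down-scaled) symbiont genomes;
* dual-infection qPCR competition trajectories -- exponential growth of a
  native and a non-native strain with multiplicative log-normal measurement
  noise;
* survival cohorts whose per-group exponential hazard is log-linear in
  (100 - relatedness), producing a monotone relatedness-survivorship
  gradient;
* binomial infection counts.

All randomness flows from a single :class:`numpy.random.Generator` seeded
per call; identical truth records and seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cophylogeny import PhyloTree, TreeNode

__all__ = [
    "TreePairTruth",
    "GenomePairTruth",
    "TrajectoryTruth",
    "SurvivalTruth",
    "simulate_tree_pair",
    "simulate_genome_pair",
    "simulate_competition_trajectories",
    "simulate_survival_cohorts",
    "simulate_infection_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# tree pairs


@dataclass(frozen=True)
class TreePairTruth:
    n_tips: int = 12
    n_switch_events: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_switch_events < 0:
            raise ValueError("n_switch_events must be >= 0")


def _yule_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree, rate 1, grown until n_tips extant lineages."""
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    now = 0.0
    while len(active) < n_tips:
        now += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = now - born if node.parent is not None else None
        left, right = TreeNode(), TreeNode()
        node.add_child(left)
        node.add_child(right)
        active.append((left, now))
        active.append((right, now))
    end = now + rng.exponential(1.0 / n_tips)
    for node, born in active:
        node.length = end - born
    return root


def _spr_tip_move(root: TreeNode, rng: np.random.Generator) -> TreeNode:
    """Prune a random tip and regraft it on a random non-adjacent edge.

    Regrafting onto the pruned tip's former sibling edge would restore the
    original topology, so that edge is excluded; every accepted move changes
    the rooted topology.  Returns the (possibly new) root.
    """
    tips = [n for n in root.postorder() if n.is_leaf()]
    if len(tips) < 3:
        raise ValueError(
            "host-switch events cannot be placed on a tree with fewer than 3 tips"
        )
    tip = tips[int(rng.integers(len(tips)))]
    parent = tip.parent
    sibling = parent.children[0] if parent.children[1] is tip else parent.children[1]
    grand = parent.parent
    if grand is None:
        sibling.parent = None
        if parent.length is not None and sibling.length is not None:
            sibling.length += parent.length
        root = sibling
        if root.length is not None:
            root.length = None
    else:
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
        if parent.length is not None and sibling.length is not None:
            sibling.length += parent.length
    # candidate regraft edges: every non-root node except the old sibling
    candidates = [
        n for n in root.postorder() if n.parent is not None and n is not sibling
    ]
    if not candidates:
        raise ValueError("no non-identity regraft position available")
    target = candidates[int(rng.integers(len(candidates)))]
    joint = TreeNode()
    tp = target.parent
    tp.children[tp.children.index(target)] = joint
    joint.parent = tp
    if target.length is not None:
        joint.length = target.length / 2.0
        target.length = target.length / 2.0
    joint.children = [target, tip]
    target.parent = joint
    tip.parent = joint
    return root


def simulate_tree_pair(
    truth: TreePairTruth,
) -> tuple[PhyloTree, PhyloTree, dict[str, str]]:
    """Co-diverged host/symbiont tree pair plus bijective tip association.

    The host is a Yule tree with tips ``host1..hostN``; the symbiont starts
    as a topological copy relabelled ``sym1..symN`` and then receives
    ``n_switch_events`` tip SPR moves.  The association maps symX -> hostX
    regardless of switches, so switches create genuine incongruence.
    """
    rng = np.random.default_rng(truth.seed)
    host_root = _yule_tree(truth.n_tips, rng)
    for i, node in enumerate(n for n in host_root.postorder() if n.is_leaf()):
        node.name = f"host{i + 1}"
    sym_root = host_root.copy()
    for node in sym_root.postorder():
        if node.is_leaf():
            node.name = "sym" + node.name[4:]
    if truth.n_switch_events > 0 and truth.n_tips < 3:
        raise ValueError("n_switch_events too large for a 2-tip tree")
    for _ in range(truth.n_switch_events):
        sym_root = _spr_tip_move(sym_root, rng)
    assoc = {f"sym{i + 1}": f"host{i + 1}" for i in range(truth.n_tips)}
    return PhyloTree(host_root), PhyloTree(sym_root), assoc


# ---------------------------------------------------------------------------
# genome pairs


@dataclass(frozen=True)
class GenomePairTruth:
    n_genes: int = 100
    gene_len: int = 900
    intergenic_len: int = 100
    subs_prob: float = 0.05
    n_inversions: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.gene_len < 1 or self.intergenic_len < 0:
            raise ValueError("invalid genome geometry")
        if not 0.0 <= self.subs_prob <= 0.75:
            raise ValueError("subs_prob must lie in [0, 0.75]")
        if self.n_inversions < 0:
            raise ValueError("n_inversions must be >= 0")

    @property
    def genome_len(self) -> int:
        return self.n_genes * (self.gene_len + self.intergenic_len)


def _place_inversions(
    truth: GenomePairTruth, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping, non-adjacent runs of 2-5 genes, as (start, n) in
    gene ordinals.  Non-adjacency keeps every inversion a distinct pair of
    strand breakpoints in the annotation."""
    taken: set[int] = set()
    runs: list[tuple[int, int]] = []
    for _ in range(truth.n_inversions):
        for _attempt in range(1000):
            k = int(rng.integers(2, 6))
            if truth.n_genes < k:
                continue
            s = int(rng.integers(0, truth.n_genes - k + 1))
            footprint = range(s - 1, s + k + 1)  # pad by one gene on each side
            if taken.isdisjoint(footprint):
                taken.update(range(s, s + k))
                runs.append((s, k))
                break
        else:
            raise ValueError(
                f"could not place {truth.n_inversions} non-overlapping inversions "
                f"in {truth.n_genes} genes"
            )
    return sorted(runs)


def simulate_genome_pair(
    truth: GenomePairTruth,
) -> tuple[str, str, pd.DataFrame]:
    """Random genome A, derived genome B, and gene coordinates for both.

    Genome A alternates gene blocks of ``gene_len`` bp with intergenic
    spacers of ``intergenic_len`` bp.  Genome B applies independent per-site
    substitutions (to a *different* base with probability ``subs_prob``) and
    then reverse-complements ``n_inversions`` segments, each a contiguous
    run of 2-5 genes.  Coordinates are 1-based inclusive; strands '+'/'-'.
    """
    rng = np.random.default_rng(truth.seed)
    unit = truth.gene_len + truth.intergenic_len
    L = truth.genome_len
    a_idx = rng.integers(0, 4, size=L)
    genome_a = _BASES[a_idx].tobytes().decode()

    b_idx = a_idx.copy()
    if truth.subs_prob > 0:
        mask = rng.random(L) < truth.subs_prob
        shift = rng.integers(1, 4, size=int(mask.sum()))
        b_idx[mask] = (b_idx[mask] + shift) % 4

    coords_b = {}  # gene ordinal -> (start0, end0_exclusive, strand)
    for g in range(truth.n_genes):
        coords_b[g] = (g * unit, g * unit + truth.gene_len, "+")

    genome_b = _BASES[b_idx].tobytes().decode()
    for s, k in _place_inversions(truth, rng):
        seg_start, seg_end = s * unit, (s + k) * unit  # genes + their spacers
        genome_b = (
            genome_b[:seg_start]
            + reverse_complement(genome_b[seg_start:seg_end])
            + genome_b[seg_end:]
        )
        for g in range(s, s + k):
            g0, g1, _ = coords_b[g]
            coords_b[g] = (seg_start + seg_end - g1, seg_start + seg_end - g0, "-")

    rows = []
    for g in range(truth.n_genes):
        rows.append(
            {
                "genome": "A",
                "gene_id": f"gene{g + 1}",
                "start": g * unit + 1,
                "end": g * unit + truth.gene_len,
                "strand": "+",
            }
        )
    for g in range(truth.n_genes):
        g0, g1, strand = coords_b[g]
        rows.append(
            {
                "genome": "B",
                "gene_id": f"gene{g + 1}",
                "start": g0 + 1,
                "end": g1,
                "strand": strand,
            }
        )
    return genome_a, genome_b, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# competition trajectories


@dataclass(frozen=True)
class TrajectoryTruth:
    """Exponential dual-infection dynamics with log-normal qPCR noise.

    ``m_native``/``m_nonnative`` are Malthusian (per-day exponential growth)
    parameters; their difference is the true selection slope.  ``noise_cv``
    is the coefficient of variation of the mean-one multiplicative error.
    """

    n0_native: float = 1e4
    n0_nonnative: float = 1e4
    m_native: float = 0.55
    m_nonnative: float = 0.523
    days: tuple[float, ...] = (1.0, 5.0, 12.0)
    n_reps: int = 5
    noise_cv: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n0_native <= 0 or self.n0_nonnative <= 0:
            raise ValueError("initial copy numbers must be positive")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def simulate_competition_trajectories(truth: TrajectoryTruth) -> pd.DataFrame:
    """Abundance table: replicate, day, strain in {native, non_native}, copies.

    copies = n0 * exp(m * t) * eps with eps log-normal, mean 1, CV
    ``noise_cv`` (eps = 1 exactly when noise_cv = 0).
    """
    rng = np.random.default_rng(truth.seed)
    if truth.noise_cv > 0:
        sigma2 = math.log(1.0 + truth.noise_cv**2)
        mu, sigma = -sigma2 / 2.0, math.sqrt(sigma2)
    rows = []
    for rep in range(1, truth.n_reps + 1):
        for day in truth.days:
            for strain, n0, m in (
                ("native", truth.n0_native, truth.m_native),
                ("non_native", truth.n0_nonnative, truth.m_nonnative),
            ):
                eps = rng.lognormal(mu, sigma) if truth.noise_cv > 0 else 1.0
                rows.append(
                    {
                        "replicate": f"rep{rep}",
                        "day": float(day),
                        "strain": strain,
                        "copies": n0 * math.exp(m * day) * eps,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass(frozen=True)
class SurvivalTruth:
    """Exponential survival with hazard log-linear in (100 - relatedness).

    Group g with relatedness R_g (a 1-100 score or ANI percent) has hazard
    h_g = baseline_hazard * exp(effect_beta * (100 - R_g) / 100); positive
    ``effect_beta`` makes hosts with less related symbionts die faster.
    Times beyond ``censor_day`` are right-censored.
    """

    group_relatedness: tuple[tuple[str, float], ...] = (
        ("native", 100.0),
        ("near", 85.0),
        ("far", 55.0),
    )
    n_per_group: int = 25
    baseline_hazard: float = 0.02
    effect_beta: float = 3.0
    censor_day: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_day <= 0:
            raise ValueError("censor_day must be > 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    def hazards(self) -> dict[str, float]:
        return {
            g: self.baseline_hazard * math.exp(self.effect_beta * (100.0 - r) / 100.0)
            for g, r in self.group_relatedness
        }


def simulate_survival_cohorts(truth: SurvivalTruth) -> pd.DataFrame:
    """Survival table: id, group, day, event (1 = death, 0 = censored)."""
    rng = np.random.default_rng(truth.seed)
    rows = []
    for group, hazard in truth.hazards().items():
        times = rng.exponential(1.0 / hazard, size=truth.n_per_group)
        for i, t in enumerate(times):
            event = int(t <= truth.censor_day)
            rows.append(
                {
                    "id": f"{group}_{i + 1}",
                    "group": group,
                    "day": float(min(t, truth.censor_day)),
                    "event": event,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# infection counts


def simulate_infection_counts(p: float, n: int, seed: int) -> int:
    """Binomial draw of infected individuals out of n at success probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    return int(np.random.default_rng(seed).binomial(n, p))
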