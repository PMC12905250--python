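#!/usr/bin/env python
"""Simulate the full synthetic study panel and write it under results/data/.

Inputs for every downstream analysis step, with ground truth recorded:
a co-diverged 12-tip host-symbiont tree pair; six donor genomes at graded
divergence from a reference (the native donor is identical); dual-infection
abundance trajectories with a -0.027/day fitness difference for the
non-native strain; and survival cohorts whose hazards follow the
relatedness gradient.
"""

import json
from pathlib import Path

from symfid.io import write_association, write_fasta, write_table
from symfid.cophylogeny import write_newick
from symfid.synthetic import (
    GenomePairTruth,
    SurvivalTruth,
    TrajectoryTruth,
    TreePairTruth,
    simulate_competition_trajectories,
    simulate_genome_pair,
    simulate_survival_cohorts,
    simulate_tree_pair,
)

SEED = 20260101
OUT = Path(__file__).resolve().parent.parent / "results" / "data"

DONORS = [  # (name, subs_prob, n_inversions)
    ("donor1", 0.00, 0),
    ("donor2", 0.02, 0),
    ("donor3", 0.05, 1),
    ("donor4", 0.10, 2),
    ("donor5", 0.15, 3),
    ("donor6", 0.20, 4),
]
RELATEDNESS_PROXY = {name: 100.0 * (1 - p) for name, p, _ in DONORS}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tree_truth = TreePairTruth(n_tips=12, n_switch_events=0, seed=SEED)
    host, symbiont, assoc = simulate_tree_pair(tree_truth)
    (OUT / "host.nwk").write_text(write_newick(host) + "\n")
    (OUT / "symbiont.nwk").write_text(write_newick(symbiont) + "\n")
    write_association(OUT / "assoc.tsv", assoc)
    print(f"trees: {tree_truth.n_tips} tips, {tree_truth.n_switch_events} host switches")

    # one seed for the whole panel: the base genome (A) is then identical
    # across donors, so every donor is a divergence of the same reference
    for i, (name, subs, inv) in enumerate(DONORS):
        truth = GenomePairTruth(
            n_genes=40, gene_len=900, intergenic_len=100,
            subs_prob=subs, n_inversions=inv, seed=SEED + 1,
        )
        ref, donor, coords = simulate_genome_pair(truth)
        if i == 0:
            write_fasta(OUT / "reference.fasta", {"reference": ref})
        write_fasta(OUT / f"{name}.fasta", {name: donor})
        write_table(OUT / f"{name}_coords.tsv", coords)
        print(f"genomes: {name} at {100 * subs:.0f}% divergence, {inv} inversions")

    comp_truth = TrajectoryTruth(
        m_native=0.55, m_nonnative=0.55 - 0.027,
        days=(1.0, 5.0, 12.0), n_reps=5, noise_cv=0.3, seed=SEED + 100,
    )
    write_table(OUT / "abundance.tsv", simulate_competition_trajectories(comp_truth))
    print(f"competition: true slope {comp_truth.m_nonnative - comp_truth.m_native:+.3f}/day, "
          f"{comp_truth.n_reps} replicates, CV {comp_truth.noise_cv}")

    surv_truth = SurvivalTruth(
        group_relatedness=tuple(sorted(RELATEDNESS_PROXY.items())),
        n_per_group=25, baseline_hazard=0.02, effect_beta=3.0,
        censor_day=30.0, seed=SEED + 200,
    )
    write_table(OUT / "survival.tsv", simulate_survival_cohorts(surv_truth))
    print(f"survival: {len(DONORS)} groups x {surv_truth.n_per_group}, "
          f"hazard effect beta = {surv_truth.effect_beta}")

    (OUT / "truth.json").write_text(json.dumps({
        "seed": SEED,
        "donors": {n: {"subs_prob": p, "n_inversions": k} for n, p, k in DONORS},
        "true_selection_slope": comp_truth.m_nonnative - comp_truth.m_native,
        "effect_beta": surv_truth.effect_beta,
    }, indent=2) + "\n")
    print(f"wrote panel to {OUT}")


if __name__ == "__main__":
    main()
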