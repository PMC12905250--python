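# symfid

Quantitative fidelity analysis of a co-diversified host–symbiont system.

Tortoise beetles harbour a drastically genome-reduced extracellular gut
symbiont that is transmitted vertically through egg-associated caplets.
When symbionts from related beetle species are experimentally swapped into
a novel host, the outcome — colonization, within-host competitive ability,
host survivorship — degrades with the genomic distance between the donor's
symbiont and the native one. `symfid` implements the quantitative backbone
of that analysis as a reusable, tested pipeline, together with synthetic
generators that plant a known truth for every stage:

1. **Co-cladogenesis** — minimum-cost duplication–transfer–loss (DTL)
   reconciliation of a symbiont tree into a host tree (cospeciation free,
   unit event costs by default), with significance from randomizing the
   symbiont-tip → host-tip association. The p-value uses the add-one
   convention, `p = (1 + #{cost_perm ≤ cost_obs}) / (1 + n_perm)`, so 100
   randomizations give a floor of 1/101 ≈ 0.0099.
2. **Genome relatedness** — fragment-based average nucleotide identity
   (ANI; 1,020-bp fragments, k-mer seeded gapped alignment on both strands)
   and a 1–100 collinearity score built from reciprocal-best orthologs
   (identity ≥ 70 %, coverage ≥ 70 %) chained into collinear blocks, scored
   over sliding gene windows and normalised so self = 100 and no homology = 1.
3. **Within-host competition** — from dual-infection qPCR time series,
   the selection coefficient of the non-native strain as the OLS slope of
   ln(non-native/native) on time (slope = ln ω), and independently the
   Malthusian selection rate r as the mean per-interval difference in
   realised growth rates. On exact exponentials both equal the difference
   in Malthusian parameters.
4. **Fidelity statistics** — Spearman rank correlation with an exact
   permutation p-value for n ≤ 8, the continuity-corrected Wilson score
   interval (the interval R's `prop.test` prints), and the Kaplan–Meier
   product-limit estimator.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study and
write their tables under `results/`:

```sh
python analysis/01_simulate_panel.py        # simulate trees, genomes, qPCR, survival
python analysis/02_cophylogeny_test.py
python analysis/03_genome_relatedness.py
python analysis/04_competition_selection.py
python analysis/05_survivorship_correlation.py
```

Step 02 tests a perfectly co-diverged 12-tip pair:

```
observed DTL cost: 0
permuted costs: min 6, max 10 over 100 randomizations
co-cladogenesis p = 0.0099 (significant at 0.01)
```

No random bijection reconciles as cheaply as the true association, so the
permutation p reaches its minimal attainable value 1/101.

Step 03 scores six donor genomes simulated at graded divergence from one
reference (substitution probability 0–20 %, 0–4 segmental inversions):

```
donor1: ANI 100.00 (expected 100.0), collinearity 100.00 with 0 inversions
donor2: ANI  97.91 (expected  98.0), collinearity 100.00 with 0 inversions
donor3: ANI  94.34 (expected  95.0), collinearity  89.00 with 1 inversions
donor4: ANI  88.61 (expected  90.0), collinearity  78.28 with 2 inversions
donor5: ANI  82.97 (expected  85.0), collinearity  67.28 with 3 inversions
donor6: ANI  78.01 (expected  80.0), collinearity  61.50 with 4 inversions
```

ANI tracks per-site divergence (fragments straddling inversion breakpoints
pull it slightly below 100(1−p)); the collinearity score additionally
penalises the rearrangements, so it falls faster down the panel.

Step 04 recovers the planted fitness difference of −0.027/day from noisy
(CV 0.3) trajectories sampled at days 1, 5 and 12:

```
selection coefficient (slope, ln omega): -0.0214/day
omega = e^slope:                         0.97884
Malthusian selection rate r:             -0.0028/day
true simulated difference:               -0.0270/day
```

A single noisy design scatters around the truth (the estimator is
unbiased: across 200 replicate simulations the mean slope is within
0.005/day of −0.027; see `tests/test_acceptance.py`). Step 05 then
correlates per-group Kaplan–Meier survivorship with donor relatedness
(Spearman with exact p at n = 6).

The same stages are available as a CLI (`symfid simulate`, `symfid
cophylo-test`, `symfid ani`, `symfid collinearity`, `symfid selection`,
`symfid stats`, `symfid run-study`) and as one orchestrated call,
`symfid.pipeline.run_synthetic_study`, which is byte-identically
reproducible under a fixed master seed.

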