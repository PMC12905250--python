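# Methods

This note documents the models behind each `symfid` stage, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions. Every number quoted here is computed by the
test suite or the analysis scripts; nothing is asserted that the code does
not reproduce.

## DTL reconciliation and the co-cladogenesis test

The reconciliation model is *undated* duplication–transfer–loss parsimony
on rooted binary trees. A symbiont node `s` mapped to host node `h` is
resolved by the cheapest of three events: cospeciation (free; the two
symbiont children descend into the two host child subtrees), duplication
(cost `d`; both children stay at or below `h`), or horizontal transfer
(cost `t`; one child stays at or below `h`, the other moves to any host
node *incomparable* to `h` — neither its ancestor nor descendant,
tips included). Each skipped host edge on a retained lineage costs one
loss (`l`). Default costs are `d = t = l = 1`. The dynamic programme
computes, per symbiont node, the exact-placement cost `c(s, h)`, the
descendant relaxation `in(s, h) = min_{h' ⪯ h} c(s, h') + l·dist(h, h')`,
and the incomparable relaxation `out(s, h) = min_{h'' incomparable} c(s, h'')`.
Note `out` takes the *loss-free* minimum of `c` over the incomparable
region: a transfer recipient lands exactly on its node, so no loss charge
applies on the recipient side. The symbiont root may map anywhere with no
stem charge. Because dated and undated variants differ only in timing
constraints the model cannot observe on these inputs, the semantics are
pinned instead by an independent oracle: exhaustive enumeration of all
symbiont-node → host-node mappings with first-principles event costing
agrees with the DP on every random instance tried (250 instances, 2–5
tips, random non-unit costs; `tests/_oracles.py`).

Congruence significance permutes the tip association by a uniform random
bijection (identity permitted) and recomputes the cost `n_perm` times
(default 100). The p-value is add-one with ties counted as extreme:
`p = (1 + #{c_perm ≤ c_obs}) / (1 + n_perm)`, bounded in
`[1/(1+n_perm), 1]`. Two consequences worth knowing:

* a perfectly congruent pair (cost 0) attains the floor `1/101 ≈ 0.0099`
  with 100 permutations, since random bijections on non-trivial trees
  essentially never reconcile for free;
* under the null (association itself random) the p-value is *conservative*,
  not uniform: DTL costs of random bijections concentrate on few values,
  and counting ties as extreme pushes p upward (measured median ≈ 0.8 on
  12-tip trees; empirical rejection at 0.05 is ≈ 0.03). The test never
  rejects more often than its nominal rate.

## Genome relatedness

**ANI.** Genome A is cut into consecutive non-overlapping fragments of
1,020 bp (the ANIb fragment length; the trailing short fragment is
dropped). Each fragment — and its reverse complement — is seeded into
genome B by exact 15-mer matches (seeds hitting > 50 positions are
ignored), the best-voted diagonal ±40 bp is aligned with edlib in
ends-free mode, and the identity is `1 − editDistance/fragment_len`.
Fragments with identity ≥ 0.30 over coverage ≥ 0.70 are retained; ANI is
the mean retained identity × 100 and `aligned_fraction` the retention
rate. No fragment retained raises a distinct "no homology" error rather
than returning 0. On substitution-only fixtures the estimator recovers
100(1−p) within 0.5 points for p up to 0.20 (100 kb fixtures); fragments
that straddle inversion breakpoints align at reduced identity, giving a
small downward bias on rearranged genomes. Fragmenting is asymmetric in
the two genomes, but A-vs-B and B-vs-A agree within one point on
generator fixtures.

**Collinearity.** Ortholog pairs are reciprocal best matches under global
(Needleman–Wunsch) gene alignment with identity ≥ 0.70 and coverage ≥ 0.70
(coverage = shorter/longer gene length; identity normalised by the longer
length). Pairs are chained, in genome-A gene order, into collinear blocks:
runs monotone in both genomes' ordinal gene positions, forward runs
requiring strand agreement and inverted runs strand disagreement, with
positional gaps of at most 5 genes on either side; runs shorter than 3
pairs are discarded. The score then scans the *smaller* genome in sliding
windows of 5 consecutive genes (stride 1, so every rearrangement
breakpoint is straddled by some window whatever its phase). A window with
at least two ortholog-bearing genes is a *comparable region*; its pairwise
synteny score is the fraction of its ortholog gene pairs lying in one and
the same collinear block. The average pairwise synteny score (APSS) times
the number of comparable regions, divided by the smaller genome's length
in bp, gives the raw score; the reported value is
`1 + 99·min(1, raw/raw_self)`, where `raw_self` is the smaller genome's
self-comparison. Self = 100 and no homology = 1 by construction, and the
score degrades strictly monotonically with the number of planted
inversions on every seed tried. The per-region score and the 1–100
anchoring are this package's own explicit definitions (the upstream tools'
internals are not published); scores are therefore comparable within this
pipeline, not across tools.

## Competition estimators

Input is a long table (replicate, day, strain ∈ {native, non_native},
copies), optionally background-corrected by subtracting the mean
no-template-control copy number (clipped at zero). Two estimators:

* **Selection coefficient.** Per replicate and day,
  `ln(copies_nonnative/copies_native)`; per day, the mean over replicates;
  then OLS of that series on day. The slope is ln ω and the reported
  headline statistic (negative ⇔ non-native disadvantage); ω = e^slope.
  Regression on per-day means mirrors fitting one line through the pooled
  series; per-replicate fitting is available via the library by passing a
  single replicate's rows.
* **Malthusian rate.** On per-day replicate-mean densities, for each
  consecutive day pair the interval rate
  `[ln(nn_t/nn_prev) − ln(nat_t/nat_prev)]/(t − t_prev)`, averaged across
  intervals. The denominator is the *elapsed interval*: dividing by the
  absolute day instead would double-count time for later intervals and
  could not return a constant rate even on exact exponentials.

Both equal `m_nonnative − m_native` exactly (to 1e−10) on noiseless data,
are invariant to rescaling all copy numbers, and the slope estimator is
unbiased under multiplicative noise (mean-one log-normal errors cancel in
the log ratio; 200 simulations at 5 replicates, CV 0.3, days {1, 5, 12}
recover the slope with |bias| < 0.005/day). Zero copies raise an error by
default; a pseudo-count policy must be requested explicitly so ratios at
the detection limit are never manufactured silently. Late adult
timepoints, where the non-native strain may be lost entirely, can be
excluded with `max_day`.

## Fidelity statistics

* **Spearman**: Pearson correlation of average ranks. For n ≤ 8 the
  two-sided p is exact by full enumeration of all n! orderings (the
  correlations in this system involve 6–7 groups, where the t
  approximation is unreliable); beyond that, the usual t approximation
  with n − 2 df. A perfect monotone arrangement of 6 points gives
  p = 2/720 ≈ 0.00278.
* **Wilson interval**: score interval with Yates continuity correction,
  evaluated at k/n shifted by the correction, with the correction capped
  at |k − n/2|/n — reproducing R's `prop.test` to 1e−9 on frozen oracle
  values (the cap makes the correction vanish at an exactly balanced
  count).
* **Kaplan–Meier**: product-limit estimator; at tied times deaths are
  processed before censorings. Cross-checked against lifelines.

## Synthetic generators

All generators draw from a single `numpy` Generator seeded per call;
identical truth records give byte-identical outputs.

* **Tree pairs**: host trees are Yule (pure-birth, rate 1, grown to
  `n_tips`); branch lengths are emitted but ignored by the undated
  reconciliation. The symbiont starts as a relabelled topological copy;
  each host-switch event prunes a random symbiont tip and regrafts it on a
  random edge other than its former sibling's, so every accepted move
  changes the rooted topology. Empirically each move costs at most one
  transfer plus three losses to reconcile. Sequence evolution along
  branches is not modelled.
* **Genome pairs**: gene blocks (default 900 bp) alternate with intergenic
  spacers (100 bp); the partner genome applies i.i.d. substitutions (to a
  different base with probability p ≤ 0.75) and then reverse-complements
  2–5-gene segments (non-overlapping and non-adjacent, so each inversion
  is a distinct breakpoint pair in the annotation). There are no indels,
  duplications, or translocations. The 0.25 Mb scale of real reduced
  symbiont genomes is down-scaled (40–100 genes, 14–100 kb) to keep the
  default analyses fast; the estimators' calibration does not depend on
  that choice beyond sampling noise.
* **Competition trajectories**: `copies = n0·exp(m·t)·ε` with ε log-normal,
  mean 1, coefficient of variation `noise_cv` — strictly positive and
  heteroscedastic on the natural scale, as qPCR copy-number error is.
  Defaults (5 replicates, days {1, 5, 12}, CV 0.3, fitness difference
  −0.027/day on a 0.55/day native growth rate) reflect the dual-infection
  design: replicate counts and noise level are conventions chosen as
  realistic for qPCR assays, since no generative values are published.
  Shared-host competition beyond the planted rate difference (e.g. density
  dependence) is not modelled.
* **Survival cohorts**: exponential failure times with per-group hazard
  `h_g = h0·exp(β·(100 − R_g)/100)` and right-censoring at `censor_day`.
  Defaults `h0 = 0.02`/day, β = 3 and censoring at day 30 put baseline
  survivorship near 0.55 and roughly double the hazard per 25-point drop
  in relatedness — a gradient strong enough to be seen with 25 animals
  per group but not deterministic. No published generative model exists;
  the log-linear hazard link is the minimal structure producing a
  monotone relatedness–survivorship correlation. Cohort effects, block
  structure and non-exponential hazards are not modelled.

Passing tests on these generators demonstrate estimator correctness and
calibration under the stated noise models — not performance on real data,
whose error structure (qPCR efficiency drift, batch effects, genome
assembly artefacts) is richer.

## Numerical conventions and problem sizes

Infinities in the DP are `math.inf`; with integer costs all comparisons
are exact. Permutation p-values compare costs with a 1e−9 tolerance.
Newick branch lengths are written to 6 decimals; coordinates in gene
tables are 1-based inclusive. Reports are JSON with sorted keys so a
fixed master seed reproduces them byte-for-byte; sub-seeds for the four
study stages are drawn once from the master seed and recorded in the
report's provenance block alongside a config hash.

Default analysis sizes — 12-tip trees with 100 randomizations, 40–100-gene
genomes, 200-replicate recovery simulations — were chosen so the full test
suite and the analysis scripts complete in a couple of minutes on one CPU
while leaving the Monte-Carlo tolerances comfortably resolvable; all are
configurable.

## Known limitations

* The reconciliation is undated; transfers constrained only by node
  incomparability can be optimistic relative to time-consistent histories.
* The permutation test is conservative under the null (ties counted as
  extreme); reported p-values near a threshold should be read with that
  in mind.
* The collinearity score's per-region definition and 1–100 anchoring are
  internal conventions; absolute values are not comparable to other
  synteny tools.
* ANI on heavily rearranged genomes is biased slightly low by
  breakpoint-straddling fragments.
* The exact-p Spearman enumerates n! orderings and is capped at n = 8 by
  default.
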