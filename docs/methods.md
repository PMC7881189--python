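# Methods

`bridgehead` reconstructs the invasion history of a globally introduced
species from unlinked biallelic SNPs by approximate Bayesian computation
with random forests (ABC-RF): candidate demographic scenarios are
simulated under explicit priors, summary statistics of the simulated and
observed data are compared through classification and quantile-regression
forests, and a step-by-step ladder of model choices narrows the candidate
space before final parameter estimation.  This note documents the model,
the numerical choices, and what the synthetic study conditions do and do
not establish.

## Demographic model

A scenario is a backward-in-time event schedule over named populations,
each with a stable diploid effective size `N`:

* **Split** — at time `t` (years before sampling) the lineages of a
  derived population join its source.  The source persists to the
  present; it may carry samples and seed further foundings.
* **Admixture founding** — a population is founded at `t` from two
  sources, drawing each founding lineage from source A with probability
  `r` (the admixture proportion) and from source B otherwise.
* **Founding bottleneck** — for `d` years immediately after its founding,
  an introduced population has effective size `N_b` (1–100 diploids for
  0–50 years), the transient founder-population phase.

Times are configured in years and divided by a configurable generation
time (default 5 years — a colony-level generation for a subterranean
termite, from colony foundation to mature alate production) before they
reach the coalescent engines.  All reported time estimates are therefore
in years with no separate back-conversion step.

The production engine maps scenarios onto `msprime`.  Foundings are
encoded as mass-migration lineage movements rather than msprime
population splits: a split would re-date the sampling time of any source
population that also founds another (msprime treats split ancestors as
activating only at the event), which is wrong for invasion scenarios
where sources are sampled in the present.  A second, independent
pure-Python lineage simulator implements the same event semantics
directly (exponential within-population pairwise coalescence at rate
`k(k-1)/2` per `2N` generations, event handling at epoch boundaries) and
serves as a distributional oracle in the tests.

## SNP ascertainment

Each locus carries exactly one mutation, placed uniformly at random on
the branches of its genealogy, so every simulated locus is polymorphic in
the pooled sample and there is no mutation-rate parameter; all per-SNP
statistics live on this ascertained scale.  Because a SNP is a site
*discovered through* its mutation, the genealogy of an ascertained SNP is
length-biased: under Poisson mutation at rate θ→0 conditioned on
polymorphism, a tree is observed with probability proportional to its
total branch length.  Both engines realise this distribution exactly with
an independence Metropolis sampler over the stream of simulated
genealogies (proposal: a fresh tree; acceptance `min(1, L'/L)`; burn-in
16 steps; one locus emitted every 2 steps).  The stationary law is
exactly the length-biased coalescent, which reproduces the closed-form
neutral expectations — folded SFS class proportions
`∝ (1/i + 1/(n−i)) / (1 + [i = n−i])` and near-fixation F_ST at deep
splits — verified in the test-suite at 50,000 loci.  The cost is one
caveat: when two consecutive proposals are both rejected (a few percent
of steps), two neighbouring loci share a genealogy (with independent
mutation placements).  Marginal distributions are exact; the residual
adjacent-locus dependence is negligible for every statistic used here and
can be removed entirely by raising the thinning constant.

## Summary statistics

For an ordered roster of `P` populations the vector contains, in a fixed
documented order: per population, the mean and variance across loci of
within-population gene diversity (with the `n/(n−1)` small-sample
correction); per unordered pair, the mean and variance of
between-population heterozygosity, the multilocus Weir & Cockerham (1984)
F_ST (ratio of sums across loci), and Nei's (1972) standard genetic
distance; and, for every choice of a target and an unordered source pair,
the admixture statistic `f3(t; a, b) = mean over loci of
(p_t − p_a)(p_t − p_b)`, whose negative values indicate the target is an
allele-frequency intermediate of the two sources.  Vector length is
`2P + 2·C(P,2) + 2·C(P,2) + 3·C(P,3)`.  Missing data are handled by
per-locus deletion within each term; a term with no usable loci raises
rather than emitting NaN.  One degenerate case is defined by convention:
a population pair monomorphic at every shared locus has F_ST 0 (no
measurable differentiation).  No sample-size bias correction is applied
inside f3 by default: observed and simulated data are compared at matched
sample sizes on ascertained SNPs, so the shared bias cancels; a flag
enables the correction.

## Random-forest ABC

**Scenario choice.** A 500-tree classification forest (`mtry = √p`) is
trained on (statistics → scenario label); each tree casts one vote for
the observed vector, and the scenario with most votes wins (ties break to
the lexicographically lowest label).  The posterior probability of the
winner is estimated Pudlo-style: a regression forest (`mtry = p/3`,
minimum leaf size 5) is trained on the out-of-bag correctness indicator
of the classifier and evaluated at the observed vector, clipped to
[0, 1].  The prior error rate is the out-of-bag misclassification
fraction.

**Parameter estimation.** A 500-tree regression forest is trained on
(statistics → parameter) for the rows of the winning scenario.  The
posterior at the observed vector is the weighted empirical distribution
of training responses with quantile-regression-forest weights: a training
row's weight is its leaf co-occupancy frequency with the observed vector,
averaged over trees (all-rows leaf weights in Meinshausen's sense, which
uses only the public forest API and is deterministic per seed).
Posterior median and the central 95% interval are weighted quantiles
(inverted-CDF rule).  A constant response column yields the degenerate
estimate equal to the constant.  Forests are ephemeral; the reference
table is the reproducibility artifact, and all randomness is seeded.

## Priors and the scenario ladder

Uniform priors with rejection sampling under strict inequality
constraints (cycle-checked; capped at 10⁶ attempts).  Defaults: US
introduction times U(50, 300) years with Hawaii constrained to predate
the mainland introductions (and Louisiana/Texas to predate Florida, which
its founding requires); bottleneck size U(1, 100) diploids and duration
U(0, 50) years; stable sizes U(100, 100 000) (native) and U(100, 50 000)
(introduced); admixture proportions U(0.01, 0.99); native regional split
U(350, 10 000) years and root split U(500, 20 000) years, constrained
`t_root > t_regional` and lying above the introduction window by
construction.  MAF during locus filtering is computed globally by default
(per-population mode available) — the choice is configurable because the
original filtering protocol does not state it.

The built-in ladder runs steps 1, 2, 2A, 2B, 3, 4, sub4, 5, 6.  Candidate
rosters follow the natural enumeration (each introduced population from
each single source or each pairwise admixture, with or without a
bridgehead); three-source admixtures are encoded as two sequential
admixture events through an unsampled staging population with its own
size but no bottleneck.  The Japanese sub-steps 2A/2B are implemented as
a genuine model choice between alternative founding sources of Okinawa /
mainland Japan (time prior U(50, 2000) years, allowing pre-modern
movement), because a model choice between alternative pool *assignments*
would change the observed vector between candidates.  Steps whose pooling
cannot be satisfied by the data at hand (e.g. the Japanese sub-steps when
localities were already pooled regionally) are recorded as skipped in the
ladder report rather than aborting the run; any other failure aborts and
preserves the partial report.  Two single-sample localities (Xinyu,
Mississippi) are excluded from every pooling.  Simulated datasets match
the observed per-population sample sizes, and the observed dataset is
thinned at random to the profile's locus count when it is larger.

Profiles: `desk` (2 000 simulations per scenario on 500 SNPs — the
default used throughout this package's own validation), `full` (10 000
on 2 000), `smoke` (reduced, for quick structural runs).

## Synthetic study conditions

The fixture generator simulates under the winning final-step topology —
Hawaii founded by admixture of the Hong Kong region (48%) and sub-eastern
Asia (52%) 138 years before sampling, Louisiana/Texas founded from the
Hawaiian bridgehead 98 years ago, Florida founded by admixture of
Louisiana/Texas (49%) and southcentral China (51%) 87 years ago — with
founding bottlenecks drawn from their priors.  The remaining nuisance
parameters take fixed, study-like point values rather than prior draws:
stable sizes of 3 000 diploids (colony-scale effective sizes typical of
eusocial insects) and native splits at 3 000 / 8 000 years, chosen so the
simulated native range shows the strong regional differentiation the real
data exhibit (regional F_ST ≈ 0.1 between the eastern Asian sub-regions
and ≈ 0.2–0.3 against southcentral China).  Without that structure the
sources of the admixture events would be nearly interchangeable and the
admixture proportions close to unidentifiable — datasets that would not
resemble the study.  Missing genotypes are injected completely at random
(default rate 6.8%) with per-population and per-individual overrides for
planting filterable defects; per-locus mean depths are log-normal around
44× (σ_log = 0.4).  The truth record carries the full parameter vector
and configuration and recreates a fixture bit-identically.

What passing on these fixtures shows: the statistics, simulators and
forests are internally consistent, the filter chain removes exactly what
it should, planted scenarios and parameters are recovered when the data
carry the signal.  What it does not show: robustness to features of real
RADseq data that are not simulated — genotyping error, allele dropout,
depth-dependent missingness, linkage within loci, inbreeding within
colonies, or ascertainment differences between the empirical SNP-calling
pipeline and the coalescent model.

## Identifiability of the introduction times

Under the stated priors the introduction *times* are only weakly
identified by allele-frequency summary statistics: the drift an
introduced population accumulates is dominated by its founding bottleneck
(intensity `d / 2N_b`, prior range 0 to ≈ 5 coalescent units), which is
confounded with the post-founding term `t / 2N`.  In simulate-then-
recover experiments the posterior medians of the Hawaii and
Louisiana/Texas times consequently sit near their constrained-prior
medians (≈ 250 and 175 years for truths 138 and 98) with wide, honest
95% intervals that do cover the truths at close to nominal rates; the
Florida time is recovered well because its constrained prior already
concentrates near the truth.  The admixture proportions, by contrast, are
identified by the f3 / distance geometry whenever the sources are
measurably diverged.  This is a property of the inference problem (wide
bottleneck priors, ascertained SNP frequencies), not of the forest
implementation; the interval calibration suite confirms the quantiles are
honest.

## Numerical choices and edge cases

* Genotype codes are alt-allele dosages in {0, 1, 2, −1 (missing)};
  phased and unphased VCF genotypes are treated identically; positions
  are 1-based.
* Filter thresholds follow their stated wording literally: individual
  missingness ≥ 30% removes (inclusive); MAF < 0.05 and observed
  heterozygosity > 0.7 remove (survival bounds inclusive at the
  threshold); the depth window [5, 200] is closed; loci with unknown
  depth pass the depth rule.  Rules are applied call-rate → MAF →
  heterozygosity → depth and removals attributed to the first failing
  rule; the surviving set is order-independent (asserted by a test).
* Nei's D clamps its log argument at 1e−12, so complete fixed difference
  yields a large finite distance instead of infinity.
* Reference tables are generated from per-row seed streams
  (`SeedSequence.spawn`), so chunked regeneration is bit-identical; all
  forest and simulator seeds derive from the caller's single seed and
  stay below 2³¹.
* Results are independent of thread counts: forests and simulators run
  single-threaded deterministic algorithms.

## Known limitations

* No recombination within loci, no sequence mutation models, no
  continuous migration between demes — discrete founding events only.
* The exact candidate rosters of the original step-by-step analysis
  beyond those identified in the main results are not enumerable from the
  primary source; the built-in ladder uses the documented natural
  enumeration and accepts user-supplied scenario files.
* Statistics are computed on ascertained SNP frequencies; nucleotide
  diversity is per-SNP, not per genomic site.
* Forest posteriors are approximations; their calibration is checked
  empirically (95% ± 5% over prior draws) rather than guaranteed.
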