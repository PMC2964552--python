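# Methods

## The data and the observation table

The unit of analysis is a panel of nine unlinked loci resequenced in two
populations: wild green foxtail (n = 29–33 haplotypes per locus) and
cultivated foxtail millet (n = 43–50), with per-locus gap-free alignment
lengths of 435–1014 bp, about 90% noncoding.  The original chromatograms
and alignments were never deposited, but the published per-locus summary
table (lengths, silent lengths, n, S, π, θ̂, neutrality tests, ρ, Rm, Hap,
Hdiv) is a sufficient observation for every inference implemented here; it
ships with the package (`milletpop/data/observed_panel.tsv`) and is the
default input of the ABC front ends.  Synthetic panels with known truth
stand in for the sequences wherever column-level data are needed.

## Alignment filtering and silent sites

A sample is dropped from a locus when more than 20% of its columns are
ambiguous (configurable; the survey's per-locus n varies accordingly), and
every column containing a gap or N in any retained sample is then removed,
so statistics see a rectangular {A,C,G,T} matrix whose width is the
"length" of the locus.  Annotation coordinates are 0-based half-open on
the alignment's own strand.  Silent length = noncoding surviving columns
plus the synonymous-site fraction of each coding codon whose three columns
all survived, counted by equal-weight (Nei–Gojobori) enumeration of the
nine one-step changes and averaged over the retained sequences; codons
broken by filtering contribute zero silent sites, a deliberately
conservative choice.  Silent lengths are therefore fractional, matching
the survey convention.

## Statistics

π uses mean pairwise differences with the n/(n−1) correction and full
mismatch counting at multi-allelic columns; per-site values divide by the
total or silent length as requested.  θ̂_W = S/(a₁L).  Tajima's D follows
the 1989 constants, with a beta-approximation p-value for significance
flags.  Fu & Li's outgroup-free D* and F* use the **original 1993
variance constants** rather than the later corrected ones: that is the
convention of the program the survey used, verified by reconstructing the
published SIGT row (n = 29, S = 10), where a singleton count of 8
reproduces both printed values (D* −2.859, F* −3.017) to three decimals
under the original constants only.  Rm is the Hudson–Kaplan four-gamete
lower bound with containment culling and a greedy disjoint-interval scan
(checked against an interval-scheduling DP oracle).  F_ST is Hudson-style
1 − H_w/H_b with both heterozygosities averaged over segregating sites
before the ratio; small negatives are reported as computed.  The SFS is
folded unless an explicit outgroup sequence is supplied; sites where the
outgroup carries a third state are skipped.  The multilocus HKA test fits
locus θᵢ, a scaled divergence time T and a population-size ratio f by a
least-squares solve of the moment equations (positivity enforced through a
log parameterization) and sums standardized deviations over all 3L cells;
the chi-square reference on 2L−2 df is a rough approximation and the
p-value should be read qualitatively.

## Per-locus recombination (ρ̂)

No published closed form unambiguously specifies the survey's per-locus ρ
estimator, so the package defines its own moment estimator on the
Hill–Weir scale: for every biallelic pair (singletons excluded) the
squared covariance D² = (p_AB − p_A p_B)² is matched against
σ²(ρd, n)·p_A(1−p_A)p_B(1−p_B), where σ² is the finite-sample E(r²)
curve, and the per-bp ρ minimizing the summed squared mismatch is scaled
by the locus length.  Matching on the D² scale (a ratio-of-averages
construction) avoids the strong upward bias of averaging r̂² itself, which
is dominated by low-frequency pairs.  Simulation calibration at n = 30,
θ_locus = 6: median estimates 4.7 / 0.44 / 14.2 at true ρ_locus
6 / 0 / 20.  Values are reported as per-locus totals (4Nc over the locus);
loci with fewer than two usable sites are not estimable (reported Na, and
skipped in cross-locus means, matching the published averaging).

## Demographic model

Backwards in time: cultivated lineages sit in a population of size N_p
(default N_a — pure bottleneck-and-recovery; the survey reports no
post-expansion size) until t₁ = t₂ − d generations ago, then in the
founder population of size N_b during (t₁, t₂], and merge into the
ancestor (size N_a, shared with the wild population) at t₂.  Migration at
4Nm-scaled rates m₁₂ (wild→cultivar, forward) and m₂₁ acts while both
populations exist.  k = N_b/d is the bottleneck severity.  N_a is anchored
to the observed wild diversity through θ = 4N_aμ with μ = 7×10⁻⁹ per site
per generation (grass synonymous-rate order); μ only matters for
converting the generation-denominated priors (t₂, d) into coalescent
units.  Each locus is simulated at its own per-site θᵢ (taken from the
observed per-locus wild Watterson estimates, i.e. mutation-rate
heterogeneity among loci is part of the model — without it the simulated
cross-locus variances cannot reach the observed ones) and at recombination
ρᵢ = (ρ/θ)·θᵢ, the grid parameterization of the inference.

## Simulation engines

`coalescent.simulate_*` delegates to msprime (ms-compatible legacy API;
haploid samples with E[π] = 4N_eμ verified empirically).  The ABC loops
run on `fastcoal`, a compact numba Hudson-style structured-coalescent
simulator whose segments carry descendant bitmasks, so infinite-sites
mutations are drawn per dying branch segment as Poisson(θ·length·lifetime)
and genotype columns read directly off the masks.  Pass-through segments
at a coalescence keep their storage, mask and birth time (their marginal
branch merely crosses a unary node), which makes the high-recombination
regime affordable.  The two engines are cross-validated in the tests:
identical E[S], E[π], Var(S) against theory, and two-sample KS agreement
of summary-statistic distributions on the two-population bottleneck model
with migration.  Fixed seeds give bit-identical output per engine.

## Rejection ABC

"Within x% of observed" is multiplicative, |sim − obs| ≤ x·|obs|; if an
observed value is exactly 0 the criterion falls back to |sim| ≤ x·SD
(cross-locus standard deviation of that statistic) — the zero case is not
defined by the survey.  Cross-locus variances are sample variances
(ddof = 1).  All randomness flows from one integer seed.

*Standard model* (per species): draw per-site θ ~ U(0, 0.03) and
ρ ~ U(0, 0.15); simulate all nine loci at their own n and L; accept when
at least 3 of the 4 cross-locus means of (S, π, Hap, Hdiv) are within 20%
of the observed means.  Rejected draws are detected early where possible:
each statistic is a sum of nonnegative per-locus terms, so a partial sum
exceeding the upper acceptance band is a definitive failure, and loci are
evaluated shortest-first so that the (superlinearly length-dependent)
expensive simulations are skipped for most rejected draws.  This
short-circuiting is exact — it never changes which draws are accepted.

*Bottleneck* (two-stage, on a ρ/θ grid value in {0, 1, 2, 5, 10}): draw
(t₂, d, k, m₁₂, m₂₁) from the printed uniform priors (t₂ 5000–15000
generations, d 100–3000, k 0.1–10, migration 0–100 in 4Nm units; t₁ is
derived, never sampled); simulate the joint two-population panel; stage 1
accepts when mean AND variance of each of (S, π, Hap, Hdiv) for the wild
sample are within 30% of the observed wild values (60% for ρ/θ ≥ 2, where
acceptance otherwise collapses); stage 2 keeps draws whose cultivated
means of (S, ρ̂, Hap, Hdiv) satisfy 3-of-4 within 30%.  Because the
package's ρ̂ estimator and the survey's differ in scale, the ρ̂ criterion
rarely passes and stage 2 acts effectively on (S, Hap, Hdiv) — consistent
with the survey's own low stage-2 counts.  Posterior summaries come from
the stage-2 survivors.

*Posterior mode*: Gaussian KDE with Silverman bandwidth evaluated on a
512-point grid over the prior-truncated support; a peak/median density
ratio below 1.2 flags a flat posterior.  Modes need at least 50 draws;
`min_survivors` lets a bottleneck run extend stage 1 (at most 2×) until
that floor is met.

*Selection scan*: parameters resampled from the stage-2 survivors, one
locus simulated per replicate, p = fraction of replicates whose cultivated
per-site π (or S, by flag — the survey does not state its test statistic)
is at most the observed value.  Small p flags diversity loss beyond the
fitted demography.

## Problem sizes

Defaults are desk-scale and configurable: the standard-model runs in the
reproduction script use 1000 accepted draws for the wild species and 350
for the cultivated one, whose acceptance rate is an order of magnitude
lower (~0.2%: its jointly low S, Hap and Hdiv pin both θ and ρ into a
small corner of the prior box); the bottleneck run uses 2000 stage-1
acceptances (the study scale of 10,000 is available by argument) with a
75-survivor floor for the density mode.  The test suite uses
further-reduced budgets (400/150 accepted draws; 1200 stage-1 at
ρ/θ = 1 with a 50-survivor floor, 150–500 elsewhere on the grid, where
the grid trend is summarized by the survivor median — far more stable
than a KDE mode at such counts).  Stage-1 acceptance at ρ/θ = 1 is ≈1%,
and ≈3% of stage-1 draws survive stage 2.

## What the synthetic generator does and does not emulate

It reproduces the panel geometry, the diversity levels, the ~90%
noncoding annotation, the outgroup (emitted as the all-ancestral
haplotype, making SFS polarization exact), optional small 1–3 bp
deletions, and the split-with-bottleneck-and-migration history with known
parameters.  It does not model sequencing error, alignment error,
heterozygote-phasing ambiguity, codon-aware selection on coding columns,
or mutation-rate variation within a locus.  Passing end-to-end tests
therefore demonstrate correctness of the estimators and of the inference
machinery under the stated model, not robustness to real-data artifacts.

## Known limitations

* The ρ/θ posterior under the standard model is weakly identified: the
  four mean statistics constrain large ρ only through a narrow haplotype-
  diversity window, so the accepted ρ/θ sample is broad (central 50% range
  roughly 2–10 for the wild observation) and its density mode sits near 2,
  well above the published point estimates (0.836 wild / 0.43 cultivated).
  The published values are reproducible as θ-mode-relative ratios only if
  the original acceptance also constrained cross-locus variances, which
  its methods text does not state; the package implements the stated
  means-only 3-of-4 rule and reports what it yields.
* The HKA p-value is a chi-square approximation; the original program used
  a simulated null.
* Tajima-D significance stars use the beta approximation, not coalescent
  simulation (available separately via the simulation engines).
* The wild population is assumed constant-sized; the observed genome-wide
  negative Tajima's D suggests mild misfit, which is part of why stage-1
  acceptance rates are low.
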