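# milletpop

Population genetics of foxtail millet (*Setaria italica*) domestication
from multilocus resequencing data of the crop and its wild progenitor,
green foxtail (*S. viridis*).

The package implements the complete analysis chain such a survey needs:

* **Per-locus diversity and neutrality statistics** — segregating sites
  *S*, nucleotide diversity π (total and silent), Watterson's θ̂ = S/(a₁L),
  Tajima's *D*, Fu & Li's *D\** and *F\** (outgroup-free, original 1993
  constants — DnaSP's convention), haplotype number and diversity, the
  Hudson–Kaplan four-gamete bound *R*ₘ, Hudson-style F_ST, shared/fixed/
  private polymorphism partitions, silent divergence *K*s, site-frequency
  spectra (folded or outgroup-polarized), and the multilocus HKA
  goodness-of-fit test.
* **Linkage-disequilibrium decay** — pairwise r² between biallelic sites
  and a nonlinear least-squares fit of the Hill–Weir drift–recombination
  expectation E(r²) = (10+C)/((2+C)(11+C)) · [1 + (3+C)(12+12C+C²)/(n(2+C)(11+C))]
  with C = ρ·d, yielding a per-bp recombination estimate and the distance
  at which the fitted curve crosses r² = 0.1.
* **Coalescent simulation** — the split-with-bottleneck-and-migration
  demography of crop domestication: an ancestral population of size *N*ₐ, a
  founder population of size *N*_b splitting at *t*₂ generations ago,
  expanding to *N*_p at *t*₁ = *t*₂ − *d*, with 4Nm-scaled gene flow in
  both directions. The bottleneck severity *k* = *N*_b/*d* is the
  identifiable quantity: small *k* means few founders for a long time.
  Two engines sit behind one interface — msprime as the reference, and a
  numba-jitted Hudson-style simulator for the inference hot path, cross-
  validated distributionally against msprime in the test suite.
* **Rejection ABC** — (i) standard-model posteriors for per-site θ and ρ
  per species (accept when ≥3 of the 4 cross-locus mean statistics S, π,
  Hap, Hdiv fall within 20% of the observed means); (ii) a two-stage
  bottleneck inference on a ρ/θ grid: stage 1 matches wild means *and*
  variances within 30%, stage 2 filters on cultivated means (3 of 4 within
  30%); (iii) a posterior-predictive selection scan giving per-locus
  p-values for diversity loss beyond demography.
* **Synthetic data** — a generator that emulates the nine-locus survey
  (435–1014 bp loci, ~90% noncoding, wild n≈29–33, cultivated n≈43–50,
  wild per-site θ≈0.006) with full ground truth, so every pipeline stage is
  testable without any sequence download.

The published per-locus observation table ships with the package and is
the default observation for the ABC analyses.

## Worked example

```python
import milletpop as mp

observed = mp.load_observed_from_table()          # packaged survey table
w = observed["wild"].table
print(round(mp.watterson_theta(27, 29, 1014), 4)) # DACP wild theta/site
print(int(w["S"].sum()))                          # wild SNP total

post = mp.abc_standard(observed["wild"], n_accept=200, seed=1)
print(round(post.mode("theta"), 4))

bott = mp.abc_bottleneck(observed["wild"], observed["cultivated"],
                         rho_over_theta=1.0, n_stage1=600, seed=1)
print(round(bott.median("k"), 2), bott.n_accepted)
```

prints

```
0.0068
147
0.0047
1.08 18
```

`0.0068` is the wild *DACP* per-site Watterson estimate and `147` the
wild SNP total, both straight from the observation table.  `0.0047` is the
posterior-mode per-site θ of wild green foxtail under the standard neutral
model at this small demonstration budget (the study-scale run in
`scripts/acceptance.py` uses 1000 accepted draws).  `1.08` is the median
bottleneck severity *k* = *N*_b/*d* among the 18 stage-2 survivors of a
quick bottleneck run at ρ/θ = 1; at the reproduction-script scale (2000
stage-1 acceptances) the posterior mode of *k* settles near 0.7 — a
moderate domestication bottleneck, consistent with the crop retaining
roughly half of its progenitor's silent diversity.

A command-line front end mirrors the library
(`milletpop synth / stats / ld / simulate / abc-standard / abc-bottleneck /
selection-scan`); see `milletpop --help`.

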