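# Methods

This note documents the statistical models behind `dompop`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want to know.

## Dominant-marker model under partial selfing

Only band presence/absence is observed; AA and Aa are indistinguishable.
With q the band-absence (null) allele frequency and F the inbreeding
coefficient, the null-phenotype probability is P0(q) = q² + F·q·(1−q).
Under equilibrium selfing at rate s, F = s/(2−s); s is an input parameter
(default 0.91, giving F ≈ 0.8349), not something the package estimates.

**Posterior allele frequencies.** For each population × locus the
band-absent count is modelled as k ~ Binomial(n, P0(q)) with a Beta(a, b)
prior on q. Posterior moments are computed by 512-node Gauss–Legendre
quadrature on [0, 1] with log-sum-exp stabilisation — exact to machine
precision at these problem sizes, avoiding the classical analytic
approximations; a 10⁶-point Riemann sum is the test oracle (agreement
≤ 1e-6). The "fitted" prior (default) maps observed null fractions k/n
through the inverse of P0 and estimates (a, b) by method of moments,
floored at 0.25 to avoid degenerate priors. Limiting behaviour: F = 0
reduces to the classic Hardy–Weinberg dominant-marker case; F = 1 treats
the locus as haploid (P0 = q).

**Shrinkage.** Posterior means are pulled toward the prior mean; the pull
grows as n shrinks. This attenuates among-population variance and hence
Fst (see below). The package keeps the Bayesian estimates everywhere for
consistency and reports the effect honestly rather than post-hoc
de-shrinking.

## Diversity statistics

* **PPL** — percent of loci with subsample band frequency strictly inside
  (0.05, 0.95).
* **Hj** — mean over loci of 2·q̂(1−q̂). Sample sizes are standardized by
  subsampling to at most 8 individuals per population, averaged over 20
  draws (configurable; the number of draws is a package choice — it trades
  Monte Carlo error against runtime and is documented in the output).
  No further small-sample correction is applied beyond the
  standardization itself.
* **DW rarity** — per population, Σ_l (band count in population / band
  count overall) divided by the population's sample size; loci absent from
  the whole dataset are excluded.

## Structure

**Fst.** Per locus, the among-population variance of q̂ on the plug-in
(ddof = 0) scale, with the mean posterior variance of q̂ subtracted as the
estimation-noise term, over the total term q̄(1−q̄); loci are combined as
a ratio of sums. This sits in the Lynch–Milligan/Weir family: the noise
term uses the same quadrature that produces q̂, so no extra model is
introduced. Two fixed, opposite populations give ≈ 1; identical
populations give 0 (negative totals are clipped). Permutation significance
shuffles individuals among populations, sizes preserved, re-estimating
frequencies per permutation; p ≥ 1/(n_perm+1) because the observed value
counts as part of the null set. Known bias: posterior shrinkage attenuates
the estimate at small n (≈ −0.02 at n = 20, F = 0.83, target 0.10);
genotyping error attenuates it further.

**Φ_PT.** AMOVA on squared Euclidean distances between binary phenotype
vectors: SS decomposition, variance components σ²_AP = (MS_A − MS_W)/n₀
and σ²_WP = MS_W, Φ_PT = σ²_AP/(σ²_AP + σ²_WP), label-permutation p.
Groups of size 1 are computed with a warning. Because both Fst and Φ_PT
carry sample-size-dependent corrections (shrinkage, df, n₀), duplicating
every individual changes them slightly (observed ≲ 0.05); they are
*nearly*, not exactly, duplication-invariant.

**Distances and trees.** Nei's standard distance from the two-allele
frequencies (q, 1−q); non-positive identities give NA with a warning.
PCoA is classical metric scaling (scikit-bio). NJ trees are built by
scikit-bio's neighbour joining; loci are bootstrapped (default 100
replicates), the majority-rule consensus topology is computed with
dendropy, and the reported tree is the full-data NJ tree midpoint-rooted
with per-bipartition bootstrap percentages as internal labels (the
consensus itself lacks branch lengths, which midpoint rooting needs).
Replicates with NA distances are dropped and counted. Mantel
isolation-by-distance uses Pearson correlation with one-sided row/column
permutation (scikit-bio), on great-circle distances between population
centroids.

## Geographic Shannon grid

A regular grid (default 25 km spacing) covers the samples' bounding box in
an azimuthal-equidistant projection centred on the sample centroid — the
projection preserves distances from the centre, and window membership is
decided by exact great-circle distances anyway. Each grid point with at
least 5 members within 35 km averages, over 100 bootstrap draws of exactly
5 individuals (without replacement; a flag allows replacement), the
plug-in binary entropy mean over loci, −[p·ln p + (1−p)·ln(1−p)] with
0·ln 0 = 0. The fixed-n resampling is the bias control; a Chao–Shen
corrected variant sits behind a flag. The index is symmetric under band
relabelling, and the grid is bit-reproducible under a fixed seed.

## Assignment and dispersal bounds

Band frequencies per population are plug-in counts with frequencies of
exactly 0 or 1 replaced by c/(n+1) and 1 − c/(n+1), c = 1 by default
(configurable) — a genotype must never have zero likelihood anywhere.
When an individual is scored against the population it was sampled from,
it is removed from the counts first (leave-one-out); a singleton home
population falls back to uninformative 0.5 frequencies with that caveat.
MLD is in log₁₀ units: allocation requires best-minus-second ≥ MLD and a
strictly positive margin (exact ties are unallocated). Exclusion p-values
rank the observed likelihood within 1000 genotypes simulated from each
candidate population (p ≥ 1/(n_rand+1)); an individual below α = 0.001
everywhere is "excluded" — a putative immigrant from an unsampled source.

The dispersal-rate bounds count, among N = allocated + excluded
individuals: distinct ordered source→destination combinations plus
excluded (lower bound — founding events), and immigrant individuals plus
excluded (upper bound). Including the excluded individuals in the
denominator is the default (a flag removes them). Distances are
great-circle km between population centroids (member means); directions
are initial bearings binned into eight 45° compass sectors; the
distance/direction summary is over distinct pairs. Percentages are
reported at one decimal, round-half-even.

The power simulation draws genotypes locus-wise Bernoulli from each
population's corrected frequencies and re-assigns them; because the same
likelihood draws are thresholded at every MLD, the non-allocation rate is
monotone non-decreasing and the wrong-allocation rate non-increasing in
MLD by construction. Note that simulating from *estimated* frequencies
makes this an optimistic power measure when populations are nearly
identical — the simulated genotypes inherit the sampling idiosyncrasies of
the frequency estimates.

## Outlier scan

**Comparisons.** Pooled dune-vs-fen contrasts at each configured
geographic scale, plus all population pairs at one scale, tagged control
when both populations share a habitat. Pooling collapses each group to a
single pseudo-deme of summed counts.

**Envelope detector.** Neutral loci are simulated at the comparison's
sample sizes: ancestral band-allele frequency resampled from the observed
per-locus pooled frequencies (so the null inherits the data's frequency
spectrum), deme frequencies Beta(p̄θ, (1−p̄)θ) with θ = 1/Fst − 1,
dominant phenotype counts Binomial(n, P0(q)) with the comparison's F. The
target Fst is the trimmed "neutral mean": loci above the 99%
He-conditional quantile are removed and the mean re-estimated; an inner
loop rescales θ until the *estimated* mean Fst of simulated loci matches
the target (the estimator's own bias cancels by construction). Observed
loci get upper-tail probabilities within He bins (12 quantile bins, ≥ 2000
simulated loci each, sparse bins merged), BH-FDR at 5% within the
comparison. 50 000 simulated loci by default — the minimum attainable
p of ≈ (bin size)⁻¹ must stay below the BH threshold for the locus count
analysed. Loci monomorphic in both groups are never outliers.

**Bayesian detector.** A fixed-dimension spike-and-slab version of the
locus/population logistic decomposition: logit F_lg = α_l + β_g, deme
null-allele frequencies q_lg ~ Beta around an ancestral p_l with scale
θ_lg = 1/F_lg − 1, binomial dominant-phenotype likelihood with the
comparison's F. Priors: α_l = δ_l·a_l with δ_l Bernoulli at 1:10 odds and
a_l ~ N(0, 1.8); β_g ~ N(−2, 1.8). Sampling is Metropolis-within-Gibbs,
fully vectorised over (comparison, locus): latent q and ancestral p by
logit random walks, a_l by random walk where included, δ_l by Gibbs with a
Carlin–Chib linking density (when excluded, a_l is refreshed from a
pseudoprior centred on the locus' moment estimate of its effect, with the
prior/pseudoprior ratio in the indicator odds — this is what lets the
chain jump into the slab at relevant values). Defaults: 4000 sweeps, 2000
burn-in, thinning 5. The Beta normaliser is cached and cancels in the
latent-frequency moves, keeping `betaln` evaluations to four full-size
calls per sweep; independent comparisons (even from different datasets)
can be stacked into one sampler call at near-constant wall time
(`spike_slab_scan`). "Strong evidence" is posterior inclusion ≥ 0.91.
Split-chain R̂ on α is computed from the retained draws; flagged loci with
R̂ > 1.1 are marked unreliable. A prior-only mode (likelihood off) must
return the prior inclusion probability 1/11 — the sampler sanity check.

**Decision rules.** Significant: flagged by both detectors in one pooled
between-habitat comparison, or by the Bayesian detector in one
between-habitat pair — and not flagged in any same-habitat control
comparison. Replicated: supported by two between-habitat pairs sharing no
population. Both rules are pure functions of the call set.

**Power at small effects.** The null noise of a pooled 6-vs-6-deme
comparison is deme-level drift: sd of the group frequency difference
≈ √(2·p(1−p)·Fst/6) ≈ 0.087 at p = 0.5, Fst = 0.09. A habitat shift of
0.5 on the logit scale moves the difference by ≈ 0.12 — a 1.4 σ effect,
essentially undetectable at a 0.5% tail or a 0.91 posterior threshold
(measured power ≈ 0 for both detectors). Shifts of ≥ 2.5 logit units are
detected with ≥ 80% power in the same design. Users planning a comparable
scan should treat sub-logit effect sizes at moderate differentiation as
out of reach for this family of detectors.

## Synthetic metapopulations

The generator emulates: island-model deme frequencies (Beta around
Beta(0.4, 0.4)-distributed ancestral frequencies, variance set by the
target Fst — the U-shaped ancestral distribution mirrors the asymmetric
band-frequency spectra typical of dominant-marker surveys); inbred
genotypes via correlated allele draws (the second draw copies the first
with probability F) collapsed to dominant phenotypes; habitat-associated
selected loci as a static ±δ/2 logit shift of the deme-level mean (a
frequency shift, not a selection coefficient — sufficient to test
detectors); selected loci draw mid-range ancestral frequencies
(0.35–0.65) so the shift is expressible rather than saturating near
fixation; first-generation migrants (full source genotype labelled with
the destination); genotyping error as independent per-cell flips at rate
ε; replicates as independent flips of the pre-error genotype (expected
discordance 2ε(1−ε)); uniform coordinates per population within
region-specific boxes.

The study-shaped preset: 38 populations (23 dune, 15 fen — the surveyed
system attempted 39 locations at a 23/16 split and the final dataset holds
38; the preset keeps the dune count) in four regions spanning ≈ 600 km of
coast plus inland Europe, sizes 3–72 summing to 422, 451 loci, s = 0.91,
Fst 0.09, ε = 0.024, 40 replicate pairs.

What the generator does **not** emulate — hence what passing tests do not
show about real data: linkage between loci (all loci independent given
deme frequencies), size homoplasy and primer-combination artefacts (locus
metadata is synthetic), isolation-by-distance (deme frequencies are
exchangeable across space), multi-generation ancestry of migrants, clonal
structure, and selection as a dynamic process.

## Problem sizes in the test suite

End-to-end checks run at desk scale by design: island-model recovery at
20 × 20 × 300; assignment power on the full 422 × 451 preset with 250
simulated genotypes × 2 iterations; outlier calibration over 20 neutral
seeds at 6 × 12 × 60 with all pairwise comparisons stacked into one
sampler; detector power over 8–10 seeds at 12 × 15 × 80. These sizes give
stable Monte Carlo behaviour for the tested tolerances; production runs
would typically raise `n_sim`, `n_perm`, `n_boot` and MCMC length by an
order of magnitude.

## Known limitations

* Posterior shrinkage biases Fst downward at small sample sizes; the
  fitted prior mitigates but does not remove this.
* The Bayesian detector with two pooled groups has limited information per
  locus (two deme observations); posterior inclusion rarely exceeds ~0.9
  unless the effect is large.
* Exclusion p-values have resolution 1/(n_rand+1): detecting p < 0.001
  requires n_rand ≥ 1000.
* The assignment power simulation is optimistic for near-identical
  populations (genotypes are simulated from the estimated frequencies).
* Nei distances can be NA for disjoint band sets; affected bootstrap
  replicates are dropped rather than imputed.
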