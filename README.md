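# dompop — dominant-marker population genetics

`dompop` is a toolkit for population-genetic analysis of **dominant
markers** (AFLP-style band presence/absence data) in **highly selfing
plants**, built around the workflow of a metapopulation survey: score a
binary band matrix, clean it, estimate allele frequencies and diversity
under inbreeding, quantify structure, assign individuals to source
populations to measure **effective long-distance dispersal (LDD)**, and
scan for **Fst-outlier loci** associated with a habitat contrast (here:
coastal dune slacks vs alkaline fens). A first-class synthetic-data module
generates metapopulations with known truth — planted migrants, planted
selected loci, genotyping error, replicates — so every stage is testable
without any external data.

It is aimed at population geneticists and molecular ecologists working
with anonymous dominant markers, where genotype classes AA/Aa are
indistinguishable and only band presence vs absence is observed.

## The models at the core

**Allele frequencies under partial selfing.** Writing q for the frequency
of the band-absence (null) allele and F for the inbreeding coefficient,
the null-phenotype probability is

    P0(q) = q² + F·q·(1 − q),        F = s / (2 − s)

for equilibrium selfing rate s. The band-absent count in a population of n
individuals is k ~ Binomial(n, P0(q)); `dompop` reports the posterior mean
of q under a Beta prior (uniform or fitted across loci), computed by
512-node Gauss–Legendre quadrature. Diversity statistics (PPL at the 5%
level, Nei's gene diversity Hj = mean 2q(1−q), the DW rarity index) and a
noise-corrected Fst on the estimated frequencies follow, plus Φ_PT (the
AMOVA analogue for binary phenotypes), Nei distances, PCoA, bootstrap NJ
consensus trees and Mantel isolation-by-distance.

**Likelihood assignment.** An individual's genotype x is scored against
every candidate population by LL(pop) = Σ_l [x_l·log₁₀ f_l + (1−x_l)·log₁₀(1−f_l)]
with zero/one band frequencies corrected by c/(n+1) and leave-one-out for
the home population. Allocation requires a minimum log-likelihood
difference (MLD) over the runner-up — MLD = 1 means ten times more likely.
Exclusion p-values (likelihood rank against genotypes simulated from a
population) identify individuals from unsampled sources. Immigrants yield
dispersal-rate bounds: distinct source→destination combinations (plus
excluded individuals) over all conclusively assigned individuals as the
lower bound, immigrant individuals over the same denominator as the upper
bound — with great-circle distances and compass-sector directions.

**Outlier scan.** Two detectors per habitat comparison, at several
geographic scales: (i) an island-model simulation envelope — neutral loci
simulated at the comparison's sample sizes, calibrated to the trimmed
neutral-mean Fst, giving heterozygosity-conditional tail probabilities
under BH-FDR; and (ii) a Bayesian spike-and-slab decomposition
logit F_lg = α_l + β_g sampled by Metropolis-within-Gibbs, flagging loci
with posterior inclusion probability ≥ 0.91. A consensus rule (both
detectors in a pooled comparison, or the Bayesian detector in a
between-habitat population pair, and never in a same-habitat control) and
a replication rule (two supporting pairs sharing no population) separate
candidate parallel divergence from noise.

## Worked example

```python
import dompop as dp

params = dp.study_shaped_preset(seed=7, n_loci=200,
    migrant_events=[dp.MigrantEvent("BNL03", "NWF01", 3)])
ds, truth = dp.simulate_metapopulation(params)

err = dp.replicate_error_rate(ds)
F = dp.selfing_to_inbreeding(0.91)
aft = dp.estimate_allele_freqs(ds, F)
fst = dp.fst_global(aft, ds, n_perm=100, seed=0)
div = dp.diversity_table(ds, F, seed=0)
at = dp.allocate(ds, mld=1.0, seed=0)
est = dp.ldd_estimate(at, ds)
```

prints (via the accompanying report lines):

```
dataset: 462 rows (40 replicates), 200 loci, 38 populations
replicate error rate: 0.051 (40 pairs)
inbreeding coefficient F = 0.8349
Fst = 0.050 (p = 0.010, 100 permutations)
mean PPL = 49.8%, mean Hj = 0.256
allocation: {'allocated': 243, 'unallocated': 179}
LDD rate between 20.2% and 22.2% (54 immigrants, 49 distinct pairs)
planted migrants recovered: 2/3
```

Reading the numbers: the preset emulates a 38-population coastal
metapopulation (selfing rate 0.91 → F ≈ 0.83) with a 2.4% per-band flip
error — the measured replicate discordance of ~5% is the expected
2ε(1−ε). The estimated Fst (0.050) sits below the generator's deme-level
target of 0.09 because genotyping error and posterior shrinkage at small
sample sizes both attenuate among-population variance; the permutation
test still finds the structure clearly (p = 0.01). At this weak
differentiation the assignment test allocates only individuals with a
clear likelihood margin (MLD = 1), and apparent among-population dispersal
is substantial — the situation in which the LDD bounds, not point
estimates, are the honest summary.

The same pipeline is available as a CLI:

```sh
dompop simulate --preset study --seed 7 --out sim/
dompop qc       --band-matrix sim/band_matrix.csv --samples sim/samples.csv \
                --locus-meta sim/locus_meta.csv --out qc/
dompop assign   --band-matrix sim/band_matrix.csv --samples sim/samples.csv \
                --locus-meta sim/locus_meta.csv --out assign/ --mld 1
```

## Layout

- `src/dompop/io_core.py` — band matrix / sample table containers and I/O
- `src/dompop/qc.py` — error rate, clones, homoplasy screen, LD scan, filters
- `src/dompop/freqs.py` — Bayesian allele frequencies, PPL / Hj / DW
- `src/dompop/structure.py` — Fst, Φ_PT AMOVA, Nei distance, PCoA, NJ, Mantel
- `src/dompop/shannon.py` — sliding-window geographic Shannon diversity grid
- `src/dompop/assignment.py` — likelihood allocation, power, LDD bounds
- `src/dompop/outliers.py` — envelope + Bayesian detectors, consensus rules
- `src/dompop/simulate.py` — synthetic metapopulations with truth tables
- `docs/methods.md` — models, assumptions, parameter choices, limitations
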