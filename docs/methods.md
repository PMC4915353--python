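# Methods

## Model

The simulator is a forward Wright–Fisher model of a constant-size haploid
population: `N` individuals, one linear locus of `L` nucleotides, discrete
non-overlapping generations. Each generation consists of

1. **reproduction** — `N` offspring drawn multinomially with probabilities
   proportional to parental fitness;
2. **mutation** — a Binomial(`N·L`, `u`) number of events, each picking a
   uniform (individual, site) and replacing the nucleotide by one of the
   other three uniformly (JC69); collisions on the same (individual, site)
   are applied sequentially;
3. **gene conversion** (optional) — a Binomial(`N·L`, (ρ/μ)·`u`) number of
   initiation events; each copies a geometric tract (support ≥ 1 nt) from a
   uniformly chosen contemporary donor over the homologous recipient
   positions, clipped at the locus end. No crossovers, no new alleles.

Fitness is multiplicative: each derived allele contributes a factor (1+s).
The selection coefficient of a new derived allele is drawn once from a
three-point-mass distribution — deleterious (s_del ≤ 0), neutral (0),
adaptive (s_adv ≥ 0) — and is a permanent property of the (site, allele)
pair while that allele survives: a second, independent origin of the same
allele reuses the same coefficient. If an allele is lost and (after the
bookkeeping sweep described below) later recreated, its class is drawn
afresh.

The population starts monomorphic for a uniformly random ancestral sequence
and evolves for a burn-in of `10·N` generations by default — several times
the ≈`2N` expected time to the most recent common ancestor, so the final
state is effectively stationary. The final sample of `n` individuals is
drawn uniformly without replacement.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `N` | 1000 | haploid population size |
| `L` | 20000 nt | locus length |
| `theta` | 0.02 | per-site 2N·u; hence u = 10⁻⁵ per site per generation |
| `n_sample` | 100 | sample size |
| `class_probs` | (0, 1, 0) | P(deleterious, neutral, adaptive) per mutation |
| `s_del`, `s_adv` | 0, 0 | per-generation selection coefficients |
| `conv_init_ratio` | 0 | gene-conversion initiation rate over mutation (ρ/μ) |
| `tract_mean` | 542 nt | mean geometric conversion tract |
| `burnin_gens` | 10·N | generations from the monomorphic start |

The *E. coli* presets set `class_probs` from genomic rates: deleterious
2×10⁻⁴ and adaptive 10⁻⁵ per genome per generation over a total genomic
mutation rate of 8.9×10⁻¹¹ × 5×10⁶ = 4.45×10⁻⁴, giving
P(del) ≈ 0.449 and P(adv) ≈ 0.0225. Weak selection means N·s = ±5
(s = ±0.005 at N = 1000). For the strong-selection preset the literal
population-scaled coefficient rescaled to N = 1000 exceeds 1, which is not
meaningful for a per-generation relative fitness increment; the preset caps
|s| at 0.5. Any |2Ns| ≫ 1 is deep in the strong-selection regime, so results
for that scenario are order-of-magnitude statements, not point predictions.

## Implementation of the population

Haplotypes live in a copy-on-write row store: after reproduction, offspring
share their parent's row; a private copy is made only when a mutation or
conversion event first touches an individual. Per-generation memory traffic
is therefore proportional to the number of events (~200 at default
parameters) rather than to N·L, which makes the full-scale replicate
(10,000 generations) run in ~10 s instead of ~50 s for a dense copy.

The "ancestral" sequence is the population's fixed background. Every 500
generations (and before sampling) derived alleles carried by all N
individuals are absorbed into it, coefficients of absorbed or lost alleles
are dropped, and fitness is re-derived exactly from the haplotypes —
removing any float drift from incremental tracking. At sampling time the
ancestral allele of a segregating site is therefore the allele its
mutation arose from, which is what the unfolded SFS needs. Rare
finite-sites pathologies are excluded from the spectrum and counted:
sites with more than two alleles in the sample, and biallelic sites whose
ancestral allele is absent from the sample (e.g. a mutation stacked on a
derived background). Tajima's D and S use all biallelic sites, which do
not require polarization.

## Statistics

* Unfolded SFS ξᵢ: biallelic sites whose derived allele is carried by
  exactly i of n sequences. Transform i·ξᵢ/Σⱼ j·ξⱼ; flat at 1/(n−1) under
  neutrality.
* Tajima's D: standard normalization constants; π from per-site allele
  counts; undefined (NaN, excluded from averages) when S = 0.
* Watterson expectation θ·L·aₙ₋₁. Note that the finite-sites model sits a
  few percent below this infinite-sites closed form at θ·L ≈ 400 because
  multi-hit sites are excluded; the simulator was checked against
  coalescent simulations with finite-sites JC69 mutation (msprime) and
  agrees within Monte-Carlo error.
* Misorientation: with q the probability that the outgroup carries the
  ancestral nucleotide, the observed spectrum mixes classes k and n−k as
  ξₖᵒᵇˢ = q·ξₖ + (1−q)·ξₙ₋ₖ. Under JC69 the probability that a segregating
  site's outgroup differs from both SNP alleles is x = 2(1−q)/3, so the
  default estimator is q̂ = 1 − 3x/2 (`jc_consistent`); the alternative
  q̂ = x/2 (`half_x`) is kept for comparability but is not consistent
  with the mixing model (it cannot produce q near 1 from small x) and
  fails the simulated-outgroup recovery test by construction. The default
  correction inverts the 2×2 mixing exactly,
  ξₖ = (q·ξₖᵒᵇˢ − (1−q)·ξₙ₋ₖᵒᵇˢ)/(2q−1); the shortcut variant without the
  factor q on ξₖᵒᵇˢ is exposed as `unweighted`. Negative corrected
  counts are clamped to zero with a warning.

## Trees and skylines

Pairwise distances are p-distances (JC69-corrected for tree building,
plain for clustering). UPGMA places each merge at half the average
inter-cluster distance, so the tree is ultrametric by construction with
branch lengths in substitutions per site. Sorted internal-node heights give
the coalescent intervals (k lineages in the k-th interval from the
present). The classic skyline estimates Nₑ·u on each interval as
t_k·C(k,2); the generalized skyline pools consecutive intervals while a
composite is shorter than ε and uses the maximum-likelihood estimate
(1/c)·Σ C(kᵢ,2)·tᵢ over the c pooled events. A trailing composite shorter
than ε is merged into its predecessor, which also absorbs zero-length
intervals produced by identical sequences. ε is selected by AIC
(2K − 2 lnL over the piecewise-constant coalescent likelihood) on a grid of
0 plus 20 log-spaced values from depth/10³ to the tree depth; ties go to
the smaller ε. The amplitude statistic is max/min of the segment estimates.

Time axis convention: 0 at the tips (present), increasing into the past.

This pipeline (UPGMA + AIC-selected generalized skyline) replaces a
Bayesian-skyline MCMC deliberately: it is deterministic and desk-scale.
Absolute amplitude magnitudes from an MCMC skyline are therefore not
comparable; the sampling-bias effects are asserted as paired directional
rank tests instead.

## Sampling-bias schemes

All N final individuals are clustered by PAM (BUILD initialization,
best-improvement SWAP, ties to the lowest index — deterministic) on the
p-distance matrix. Uniform sampling draws one individual per cluster with
k = 100; clustered sampling draws 100 from one uniformly chosen cluster
with ≥ 100 members (k = 10); mixed sampling draws 91 from a focal cluster
plus one from each of the remaining nine. Clusters are not constrained to
be monophyletic, mirroring how real strain panels are assembled from
coarse typing.

## Synthetic data: what it does and does not emulate

The simulator *is* the data source; there is no external data. It emulates
a constant-size, panmictic, haploid population with equal nucleotide
frequencies, point-mass selection and contemporary-donor conversion. It
does not emulate population structure, demographic change, variable
mutation rates along the genome, codon structure, or transition/transversion
bias — so passing tests show that the *inference methods* are biased under
selection/conversion/sampling even in this idealized setting, not that the
simulator reproduces every property of real bacterial genomes.

One property of the conversion model deserves a note: copying from a
contemporary donor adds pair-coalescence at relative rate
≈ (ρ/μ)·tract·θ/N. At the study scale (N = 1000, ρ/μ = 1) this is ~1 %, so
"conversion leaves the mean number of segregating sites unchanged" holds
there; at strongly reduced N or inflated ρ/μ the same physical process
visibly depresses diversity. The small-scale property test of
mean-preservation therefore runs at parameters where this term is well
below the replicate standard error, and the variance-reduction property is
demonstrated at ρ/μ = 10 where it is strong.

## Numerical and design choices

* RNG: one master seed per experiment; replicate r uses
  `SeedSequence(seed, spawn_key=(r,))`, so any replicate is reproducible in
  isolation and parallel execution cannot change results.
* Problem sizes: the full-scale batches used by the acceptance checks are
  20 neutral and 10 replicates per selection scenario — the neutral batch
  is larger because S has coalescent-scale variance (SD ≈ 0.5·E[S] under
  full linkage) and its comparison is two-sided. Property tests run at
  reduced N and L chosen so that the tested effect exceeds 3 SE.
* Ultrametricity tolerance 10⁻⁹ (relative to depth); Newick round-trips
  write 17 significant digits.
* Degenerate inputs: S = 0 makes the transformed SFS and Tajima's D
  undefined (error / NaN, never silently 0); a zero minimum makes the
  skyline amplitude undefined; classic skylines flag zero-length intervals.
* The per-interval classic-skyline estimates are exponentially distributed
  around the true scaled size, so parameter-recovery tests compare their
  *mean* (unbiased), not their median (biased by ln 2).

## Known limitations

* No population structure and no demographic change — by design, constant
  size is the point of the study.
* The strong-selection scenario depends on the |s| cap; only the order of
  magnitude of its diversity level is meaningful.
* PAM is exact local search, not the global optimum; for k = 100 on 1000
  individuals runtimes are seconds, but quadratic memory limits N to a few
  thousand.
* The generalized-skyline likelihood ignores tree-estimation error: the
  UPGMA tree is treated as observed, as is usual for skyline plots.
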