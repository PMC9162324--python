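# Methods

## The test and its model

The statistic compares the nonsynonymous:synonymous ratio among polymorphisms
shared between two populations to the same ratio among polymorphisms private
to one of them: Z = (S_N/S_S)/(R_N/R_S). Its logic is that synonymous
mutations are neutral and trace the shared genealogical history, while
deleterious nonsynonymous mutations are young, rare, and mostly private;
only balancing selection (or neutrality) keeps nonsynonymous variants
segregating in both populations. The null Z = 1 holds when nonsynonymous
mutations are a mixture of neutral and strongly deleterious effects, because
the neutral fraction f cancels between shared and private classes.

The estimator α_b = 1 − 1/Z rests on an explicit expectation model. Writing
θ = 4N_e·u, ρ for the private proportion of polymorphisms, W for Watterson's
coefficient (a supplied dimensionless factor — it cancels in α_b, so the
package never computes it from sample size), f for the neutral nonsynonymous
fraction, b for the number of balanced nonsynonymous polymorphisms and x for
the neutral variants each maintains in linkage disequilibrium:

    R_S = θρW                    R_N = θρW·f
    S_S = θ(1−ρ)W + b·x          S_N = θ(1−ρ)W·f + b + b·x·f

from which α_b = 1 − (S_S·R_N)/(S_N·R_S) = b/S_N exactly. The identity is
exercised numerically over random parameter draws in the test suite. The
model's assumptions — all balanced polymorphisms predate the split, no
private balanced polymorphisms, no slightly deleterious mutations (SDMs) —
all bias α_b downward in realistic data, so the estimate is conservative;
α_b may be negative when Z < 1 and is reported untruncated.

## Frequency handling

Allele frequencies are folded (minor-allele frequency, MAF ∈ [0, 0.5]);
no ancestral-state polarisation is attempted. The frequency of a shared
polymorphism is taken in the *focal* population — the one contributing the
private polymorphisms — so a frequency filter applies symmetrically to both
categories (filtering only private sites would compare SDM-free private
polymorphism against SDM-laden shared polymorphism and manufacture spurious
Z > 1). Sites are binned in folded-MAF bins of width 0.1; bins are half-open
(lo, hi], so MAF exactly 0.1 falls in the lowest bin and is excluded from the
pooled strictly-above-0.1 set, and MAF 0.5 falls in the top bin. Bins with
any cell below 20 polymorphisms are flagged unreliable (not deleted), and
gene sets need at least 100 polymorphisms above MAF 0.1 before their pooled
estimate is considered stable.

"Polymorphic" means 0 < frequency < 1 in the population sample; fixed
differences and monomorphic sites enter no cell. Functional classes other
than nonsynonymous/synonymous are excluded. Shared status requires the same
ref/alt pair at the site in both populations (the input convention provides
this); indels, MNPs and multiallelic records are dropped at read time.

## Significance and uncertainty

Single tables use Pearson's chi-squared test of independence (1 df, no Yates
correction by default — the counts to which the test is applied are large
enough that the correction is second-order; a flag enables it) or, for
single genes, a one-tailed Fisher exact test in the direction Z > 1.
Multi-gene uncertainty comes from a gene-level bootstrap: genes are the unit
that captures all between-gene variance (in humans, linkage decays well
within the typical inter-gene distance). Genes are resampled with
replacement, the four counts summed, and the statistic recomputed; intervals
are percentile intervals (default 100 replicates at 95%, configurable
upward), the standard error is the SD of replicate statistics, and
replicates with an undefined statistic (a resampled zero cell) are dropped
and counted rather than imputed. Pooled statistics are always
ratio-of-sums, never means of per-replicate ratios (which are biased).

## The simulator

A forward Wright–Fisher model of a coding locus in a diploid ancestral
population of size N (default 200) that equilibrates for 15N generations and
then splits — by duplication (two copies of size N), vicariance (fractions
of N) or dispersal (the ancestor persists; a daughter buds off) — with
optional exponential expansion (to a multiple of the initial size by 21N
generations after the split) and symmetric conservative migration (a
fraction m of each population replaced by migrants per generation; the
migration settings 0.01 and 0.001 are interpreted as per-generation
fractions).

Sites are tracked as independent allele-frequency trajectories: deterministic
selection with genotype fitnesses 1, 1+hs, 1+s followed by binomial drift,
and per-site biallelic mutation (a mutation landing on an occupied site is
redrawn, keeping sites biallelic). Sites are therefore unlinked. This is the
central simplification of the engine: it cannot generate hitchhiking
variation around a balanced site (the x of the expectation model stays 0 in
simulated data) or any interference among deleterious mutations, and the
configured per-site crossover rate is inert. None of the simulation
experiments shipped here depends on linkage — the test statistic itself uses
only marginal site frequencies — but conclusions about linked neutral
diversity cannot be drawn from this engine. Intronic positions are neutral
and excluded from count tables, so under the unlinked model they are not
simulated at all.

Within exons, positions at codon offset 3 are synonymous and offsets 1–2
nonsynonymous — a deterministic 2:1 nonsynonymous:synonymous rule that makes
counts reproducible. Deleterious selection coefficients are drawn from a
gamma DFE on the N_e·s scale (human preset: shape 0.23, mean N_e·s = 425;
Drosophila: 0.35 and 1,800; N_e is the ancestral size), floored at s = −0.99
(effectively lethal). Dominance follows h = 1/(1/θ_intercept − θ_rate·s)
with θ_intercept = 0.5 and θ_rate = 41225.56, so neutral mutations are
codominant and h falls toward 0 with increasing |s|.

A balanced polymorphism is modelled by negative frequency-dependent
selection with s(p) = s₀(1 − p/p_eq): zero at the equilibrium frequency
p_eq (drawn uniformly on (0,1) per replicate), positive below and negative
above it, with N·s₀ = 20 anchored to the ancestral size. This restoring-force
parameterisation is the package's own concrete choice for "equilibrium
strength Ns = 20"; the qualitative behaviour (a stable interior equilibrium,
persistence far beyond neutral expectation, preferential loss of low-p_eq
alleles) is insensitive to the exact functional form. The allele enters as a
single copy at the centre of each exon 5N generations before the split;
replicates in which no balanced allele segregates in both populations at the
sampling time are discarded, and the discard count reported — the realised
equilibrium-frequency distribution is therefore biased toward common
alleles, as it should be.

Two engines share the model. `run_scenario` simulates one replicate with
all sites together and implements discard-and-redraw (fresh seed stream per
attempt, capped). `run_batch` vectorises thousands of replicates and
exploits the independence of unlinked sites: balanced-allele trajectories
are simulated separately over many attempts, survivors are paired one-to-one
with independently simulated backgrounds, and retention masks are applied at
each sample time — exact under the unlinked-sites model and an order of
magnitude cheaper than rejection on full replicates. The batch engine uses
one seeded generator (recorded in its manifest) rather than per-replicate
seeds, which vectorisation precludes.

## Desk-scale study conditions

At the literal human rates (μ = 2.5e-8 per site per generation) a 288-bp
locus in a population of N = 200 is almost never polymorphic, which is why
the original characterisation of this test needed millions of replicates.
The package's experiments instead inflate the mutation rate 1,000-fold
(μ = 2.5e-5, per-locus θ ≈ 5.8, roughly 35 segregating sites per
population), which leaves per-site trajectories unchanged while making each
replicate informative, and use 10³–10⁴ replicates. Pooled-count Monte-Carlo
standard errors for Z use the delta-method approximation
SE(ln Z) = sqrt(1/S_N + 1/S_S + 1/R_N + 1/R_S). A `rescaled()` helper also
supports the classical joint rescaling (N down, μ, r and s up), for users who
want to trade population size against rates instead.

The synthetic fixture generator (`balsel.io.generate_fixture`) emulates
1000-Genomes-like two-population SNP input — VCF with genotypes, population
map, annotation table — with an exactly known shared/private composition
per frequency bin, placing allele counts on the genotype grid so the full
classify→bin→count pipeline reproduces the target tables without error. It
makes no attempt to emulate linkage disequilibrium, mutation-rate
heterogeneity, genotyping error or admixture; end-to-end tests built on it
demonstrate bookkeeping correctness, not robustness to those features of
real data.

## Numerical and design notes

- Ratio statistics raise a named error identifying the zero cell rather than
  returning infinities; degenerate Fisher tables return p = 1.
- Count containers accept real values so expectation tables and bootstrap
  sums flow through the same code path; Fisher requires integer counts.
- Recombination splits operate at gene level on the median per-gene rate,
  ties to the low partition.
- In the recovery experiment, "true α_b" counts only flagged balanced
  mutations among shared nonsynonymous sites (matching b/S_N); negative
  inferred values are truncated to zero only in the display ratio.
- The single-gene power summary is the fraction of no-balancing replicates
  whose Z exceeds the median of the balancing arm (≈0.5 means the
  distributions coincide); the choice of overlap summary is the package's.

## Known limitations

No linkage (see above); no background selection, biased gene conversion or
admixture in the simulator; no ancestral-state polarisation (by design); no
multiple-testing machinery beyond reporting nominal p-values; the
three-population human demographic presets used in large-scale human
analyses are encodable through the demography schema but ship untested.
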