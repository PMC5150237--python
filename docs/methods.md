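# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and what the test suite does and does not show.

## The choice model

Each offspring is treated as the outcome of one maternal choice among the
sexually mature males present in her colony during the conception season
(the *candidate pool*, which always contains the assigned father). Two
complementary analyses ask whether chosen males differ systematically
from their pool-mates in MHC dissimilarity (to the mother) or diversity.

### Indices

Genotypes are pooled allele sets: MHC amplicons in non-model species
amplify several unresolvable loci, so an individual's class-I (or
class-II) genotype is the set of distinct alleles observed, treated as
one super-locus. For a female set F, male set M, and amino-acid Hamming
distance d(·,·) between allele translations:

* MALDis = |M \ F|, CALDis = |M Δ F| (integers);
* μAADis = mean d over allele pairs among the non-shared alleles. The
  phrase "among the non-shared alleles" is ambiguous; the default takes
  all unordered pairs *within* the symmetric difference
  (`mode="within_symdiff"`), the alternative takes female-only × male-only
  *cross* pairs (`mode="cross"`). Both are implemented and tested. A
  couple sharing all (or all but one) alleles has no pairs: the value is
  carried as `defined=False` and such couples are excluded from means and
  model fits, with the exclusion logged.
* MALDiv = |M|; MAADiv = Σ d over unordered pairs within M.

Distances are plain amino-acid mismatch counts on equal-length
translations — no alignment, no physicochemical weighting.

### Randomization test

For an index I, the observed statistic is the mean of I over real couples
(diversity indices: over real fathers). Each of B replicates redraws,
independently per offspring, one male uniformly from that offspring's
*genotyped* candidate set (with replacement across offspring) and records
the mean. The two-tailed p-value is the +1-corrected fraction of
replicate means at least as far from the null center as the observed
mean.

The null center is the exact expectation of the randomized mean (the mean
over events of each pool's value mean). The mean of simulated means
estimates exactly this quantity; using the analytic value instead removes
its O(1/√B) noise, which otherwise flips exact ties at the two-tailed
boundary — the index means sit on a discrete grid, so tie handling is not
a technicality. With this choice the Monte Carlo p converges to the
exact-enumeration p (the suite checks agreement within 0.01 at B = 10⁵).
A median center and an uncorrected proportion-style p are available as
options.

### Mixed models

The choice table has one row per (offspring, genotyped candidate) with
CHOSEN ∈ {0,1}; an offspring enters iff its father is genotyped and at
least one further candidate is genotyped, and (for dissimilarity indices)
its mother is genotyped — which is why dissimilarity and diversity
analyses can retain different couple counts from the same data. Models
are binomial-logit GLMMs with four crossed Gaussian random intercepts:

    CHOSEN ~ MHC_INDEX [* factor(TAARlocus)]
             + (1|COLONY) + (1|YEAR) + (1|CANDIDATEFATHER) + (1|MOTHER)

**Fitting.** No installed Python library fits crossed-random-intercept
binomial GLMMs by ML, so the engine is implemented here: Laplace
approximation in the spherical parameterization u = σv, with an inner
penalized IRLS profiling (β, v) jointly at fixed σ and an outer
Nelder-Mead over the four σ ≥ 0 (bounds [0, 8]). This is the nAGQ=0-style
scheme of lme4; on a reference dataset the fitted slope, random-effect
SDs and −2 log L agree with `lme4::glmer(..., nAGQ=0)` to ~1e-4 (the test
suite reruns this comparison through Rscript). The inner loop is
numba-compiled; one fit of a ~700-row table takes ~10–50 ms, which is
what makes bootstrap calibration studies feasible.

Numerical details: fitted probabilities are reached through a ±35 clamp
on the linear predictor; the normal-equations matrix gets a 1e-12 ridge;
PIRLS uses step-halving on the penalized deviance with relative
convergence tolerance 1e-10 (1e-8 inside bootstrap refits); outer
tolerances default to xatol 5e-3 / fatol 5e-4 and are loosened to
8e-2 / 5e-2 for bootstrap refits, which changes −2 log L by ≲0.01 —
well below the resolution of a 99–199-draw bootstrap null. Fixed-effect
SEs come from the (β, v) information matrix at the optimum. The same
approximation is used for every model entering a likelihood-ratio
comparison, and the bootstrap calibrates the statistic, so no conclusion
rests on the absolute accuracy of the Laplace likelihood.

**Inference.** Fixed effects are tested by parametric-bootstrap LRT:
simulate responses from the fitted null model (fresh Gaussian random
effects + Bernoulli noise), refit both models, and compare the observed
statistic 2(ℓ_full − ℓ_null) to the replicate distribution;
p = (1 + #{T_b ≥ T_obs}) / (n_eff + 1) over converged replicates, with
the result flagged if more than 5% of refits fail. Choice-probability
curves are fixed-effects-only inverse-logit predictions with percentile
bands from bootstrap refits; slope CIs use the bootstrap-SD normal
interval by default (stable at the n_boot used in routine runs), with a
percentile option. TAAR moderation is tested as
`MHC_INDEX * factor` vs `MHC_INDEX + factor`, the factor being a property
of the mother (heterozygosity status, or presence of a named allele)
attached to all her rows. The index enters untransformed by default; a
standardize flag exists for numerical stability and reports
back-transformed slopes. No multiple-testing correction is applied across
indices.

## Amplicon genotyping

The workflow calls alleles without sequencing replicates:

1. **Demultiplexing** by exact barcode and primer match; any mismatch in
   a flank discards the read (base qualities, if present, are ignored).
   Retained reads are trimmed to the inter-primer region; equal amplicon
   length per gene is assumed thereafter (deviant lengths are dropped and
   logged — there is no indel alignment).
2. **Chimera filter**, reference-free and abundance-ordered: a read is
   flagged when some prefix/suffix splice of two distinct, strictly more
   abundant sequences reproduces it with at most `max_mismatches`
   (default 0) mismatches, strictly fewer than its best single parent.
   The exactness requirement reflects the mechanism — PCR chimeras are
   exact splices of their templates — and is what keeps genuine
   low-abundance alleles unflagged: true alleles are mutation clouds
   around a shared ancestor, so a merely-*closer* two-parent splice is
   common and a purely comparative rule over-flags drastically (~18% of
   reads in simulation, against a 2% true rate).
3. **Homology filter**: the in-frame translation must be stop-free and at
   least `min_identity` (boundary inclusive) identical to a reference
   protein — this is what removes pseudogenes and null alleles.
4. **Oligotype calling**: per-column Shannon entropy over the pooled
   alignment; columns above `entropy_threshold` define each read's
   oligotype; an oligotype is called in an individual when its reads meet
   both `min_reads_per_allele` and `min_fraction_per_allele`; alleles
   seen in fewer than 2 individuals are deleted everywhere; individuals
   below `min_alleles_per_individual` are dropped for that gene. Allele
   names are assigned by pooled abundance; each allele carries a modal
   representative sequence. Ties everywhere are broken lexicographically,
   so the pipeline is invariant to read input order.

**Threshold choices.** The package defaults (entropy 0.2 nats, fraction
0.05) are deliberately conservative configuration defaults, not derived
values. For data with per-base error rate e ≈ 0.005 the operating point
can be derived: an error-only column has entropy
−(1−e)ln(1−e) − e·ln(e/3) ≈ 0.037 nats, while a true variant column whose
rarest carrier allele contributes ~1% of pooled reads has ≈ 0.056 nats,
so the acceptance and pipeline runs use 0.045 — above the error floor,
below the faintest real signal. Likewise, with up to 6 alleles per
individual and a clean-oligotype read fraction of (1−e)^(#entropy
columns) ≈ 0.42, the expected per-allele read fraction is ≈ 0.07 with SD
≈ 0.011; a 0.05 cutoff sits only ~1.8 SD below that mean and
systematically undercalls 5–6-allele individuals, so those runs use 0.03
(~3.6 SD below the mean, still >5× the per-oligotype error background).

**Recoverable truth.** The single-individual-allele filter is part of the
design (it is what removes one-off artifacts when no replicates exist),
so a perfect caller returns the *filtered* truth. Recovery is therefore
measured against `recoverable_genotypes(truth)`: truth minus
alleles carried by <2 individuals, minus individuals left below the
per-gene minimum. Under this definition, noiseless recovery is exact and
the noisy study condition (depth 300, e = 0.005, 2% chimeras) recovers
≥95% of individuals exactly.

**Validation.** Mendelian trio check: any offspring allele absent from
mother ∪ father is a violation; optional correction removes offending
alleles (never emptying a genotype). Repeatability between replicate
samples defaults to the Jaccard agreement |A∩B|/|A∪B| averaged over pairs
and genes (an exact-match variant is available) — the agreement metric
itself is a package choice, as is the minimum-alleles filter
(per-gene defaults MHC-I 3, MHC-II 2, TAAR 1, matching the observed
per-individual ranges).

## Linkage disequilibrium

Genotypes reduce to categories (unordered allele pair for diploid loci;
the whole allele-set profile for pooled MHC genes, since single-locus
genotypes are unrecoverable). The statistic is the fixed-margins
contingency-table probability (∏rᵢ!∏cⱼ!)/(N!∏nᵢⱼ!); the null permutes one
locus's genotypes across individuals; p counts permuted tables with
probability ≤ observed (+1-corrected). This replaces a Markov-chain
implementation of the multi-allelic exact test with a plain permutation
scheme testing the identical null hypothesis — "dememorization steps"
have no analogue and the result records the permutation count only. On
2×2 tables the ordering coincides with the two-sided Fisher exact test
(checked within 0.01). Since margins are permutation-invariant, only
cells with nᵢⱼ ≥ 2 contribute to the comparison, which keeps sparse
profile×profile tables cheap.

## Synthetic populations

The generator emulates the study design, not bat demography: colonies
hold males and females; each (colony, season) has a candidate pool whose
size is drawn from a three-block mixture (uniform on 2–4 w.p. 0.58, 5–16
w.p. 0.01, 17–21 w.p. 0.41 — a mean of 9.6 with SD 8.1 inside [2, 21]
forces near-bimodality, matching small harems vs large aggregations; the
mixture attains mean ≈9.6, SD ≈7.9, the closest a bounded distribution
gets). Pools draw colony males first and top up with visiting males.

Allele catalogs are generated by mutating one ancestral in-frame sequence
per gene (1 + Poisson(0.08·L) substitutions per allele, stop codons
rejected), giving amino-acid distance matrices with realistic spread.
Pooled-MHC allele frequencies follow a harmonic (Zipf-like) spectrum, so
a few-hundred-individual sample carries every catalog allele and the tail
alleles appear in only a handful of individuals; diploid loci use a
geometric spectrum, except TAAR3 which defaults to (0.66, 0.30, 0.02,
0.01, 0.01), reproducing carrier fractions of roughly 90%/55% for its two
common alleles. Genotype draws: pooled genes take k ~ Uniform{min..max}
distinct alleles; diploid genes take two independent draws
(Hardy-Weinberg), reported as sets of 1–2 alleles.

Mate choice is conditional-logit: within the pool,
P(father = m) ∝ exp(β · index(mother, m)), so β = 0 is uniform random
choice and β → ∞ picks the argmax. A per-mother β function supports
moderated preferences (e.g. only TAAR3-heterozygous females choosy).
An undefined index value (μAADis with no non-shared pairs) contributes
weight exp(0) — the candidate is neither favored nor penalized.

Offspring inheritance for pooled genotypes is necessarily invented (the
real locus structure is unresolved): the offspring draws its set size k
uniformly within the gene's bounds, takes ⌈k/2⌉ alleles from one parent
(coin flip which) and the rest from the other, deduplicates, and tops up
from the parental union if below the gene minimum — guaranteeing zero
Mendelian violations by construction. Diploid loci transmit one allele
per parent. Reads per individual draw alleles uniformly; chimeras splice
two of the individual's alleles at a uniform breakpoint; errors are
i.i.d. substitutions. No indels, no quality scores, no survival or
dispersal dynamics.

Because the conditional-logit generator is not literally the marginal
GLMM being fitted, recovered slopes are mildly attenuated relative to the
generating β (≈0.48 recovered at β = 0.5 in the suite's conditions);
parameter-recovery checks account for this by testing the mean estimate
within ±0.1 of β.

All randomness descends from one master seed through named substreams
(`SeedSequence` spawn keys from CRC32 of the stream name), so any stage
can be rerun in isolation bit-identically.

## Problem sizes used by the test suite

Calibration and power studies run at the study's data scale — 133
offspring per dataset, pools of mean ≈9.6 (2–21), and ~45% of males
genotyped so that choice tables hold ~130 chosen and ~480 candidate rows
— with replicate counts chosen for a routine CI run: 400 datasets for
randomization and LD type-I error (B = 2000 / 499 permutations), 150
datasets for bootstrap-LRT type-I error (n_boot = 99), 50 simulations for
slope recovery and CI coverage (~500 events each, n_boot = 59 normal-
bootstrap CIs), 30 + 40 datasets for interaction power and level
(n_boot = 99), 25 datasets × 8 loci for the microsatellite control, and
100 individuals at depth 300 for genotyping recovery. Acceptance bands
are two-sided binomial bands around the nominal level at those replicate
counts.

## What passing tests show — and what they do not

The suite demonstrates internal statistical correctness: exact index
arithmetic, MC–exact agreement, honest type-I error of all three test
families under the generator's null, power against built-in preferences,
exact genotype recovery under the stated noise model, and agreement of
the GLMM engine with lme4. It does not validate field realism: real
amplicon noise is not i.i.d. (PCR bias, quality-correlated errors,
indels), real pedigrees carry uncertainty, real populations have
structure the generator lacks (relatedness, dispersal, unequal male
availability), and the pooled-MHC inheritance model is a stand-in. Known
limitations: no locus assignment of MHC alleles, no supertype or
physicochemical distances, no model selection over random-effect
structures, no sequential Monte Carlo p-values, and equal-length
amplicons only.
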