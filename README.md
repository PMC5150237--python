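# mhcmate

Statistical toolkit for testing **MHC-dependent mate choice** from
parentage data in wild populations — built around the mating system of the
greater sac-winged bat (*Saccopteryx bilineata*), where females choose
among the sexually mature males of their colony each conception season and
paternity is known from microsatellite parentage analysis.

It provides, as a library and a CLI:

* **MHC genetic parameters** on pooled multi-locus genotypes — three
  couple dissimilarity indices and two male diversity indices:

  | index | definition |
  |---|---|
  | MALDis | \|M \ F\| — male alleles the female lacks |
  | CALDis | \|M Δ F\| — total non-shared alleles in the couple |
  | μAADis | mean amino-acid Hamming distance among non-shared alleles |
  | MALDiv | \|M\| — the male's distinct allele count |
  | MAADiv | Σ pairwise amino-acid distances within the male's alleles |

* **Candidate-pool randomization tests**: the observed index mean over
  real couples vs. its distribution under B random re-assemblies, drawing
  one male per offspring uniformly from that offspring's genotyped
  candidate pool (father included, with replacement); two-tailed p around
  the null expectation of the mean. An exact-enumeration version serves as
  oracle on small problems.

* **Choice-table mixed models**: one row per (offspring, genotyped
  candidate) with a binary `CHOSEN` response, fitted as a binomial GLMM

  `CHOSEN ~ MHC_INDEX + (1|COLONY) + (1|YEAR) + (1|CANDIDATEFATHER) + (1|MOTHER)`

  by Laplace-approximated ML (own numba-accelerated engine, validated
  against `lme4::glmer`), with parametric-bootstrap likelihood-ratio
  tests, bootstrap confidence bands for choice-probability curves, and
  TAAR-genotype interaction tests (`MHC_INDEX * factor(TAARlocus)`).

* **Amplicon allele calling without replicates**: exact barcode/primer
  demultiplexing, a reference-free exact-splice chimera filter, a
  translated-homology filter (drops pseudogenes/stop codons), oligotype
  allele calling on high-Shannon-entropy alignment columns,
  single-individual-allele and minimum-allele filters, Mendelian trio
  checking/correction, and replicate repeatability.

* **Linkage disequilibrium**: a permutation analogue of the multi-allelic
  Fisher exact test on genotype × genotype contingency tables (pooled MHC
  genotypes enter as allele-set profiles).

* **A synthetic population generator** that emulates the study design —
  colonies, per-season candidate pools (mean ≈ 9.6, SD ≈ 8, range 2–21),
  pooled MHC genotypes (50 class-I alleles, 3–6 per individual; 25
  class-II, 2–4), diploid TAAR loci (9/5/8 alleles) and 8 neutral
  microsatellites — with a tunable softmax mate preference
  (P(father = m) ∝ exp(β · index)), Mendelian-consistent offspring, and
  simulated amplicon reads with substitution errors and chimeras.

## Worked example

```python
import numpy as np
from mhcmate.simulate import (default_config, generate_catalogs,
                              generate_population, simulate_choices,
                              PreferenceSpec)
from mhcmate.indices import aa_distance_matrix
from mhcmate.inference import (build_choice_table, ModelSpec,
                               lrt_parametric_bootstrap)
from mhcmate.randomization import mc_randomization_test

cfg = default_config(n_colonies=8, n_females=100, n_males=60, n_years=8)
cats = generate_catalogs(cfg, seed=1)
pop = generate_population(cfg, cats, seed=2)
D = aa_distance_matrix(cats["MHC1"])

# females prefer MHC-I diverse males (log-odds slope 0.5 per allele)
events, _ = simulate_choices(pop, PreferenceSpec("MALDiv", 0.5, "MHC1"),
                             n_offspring=300, seed=3, D=D)
gt = pop.genotype_table()

rand = mc_randomization_test(events, gt, "MHC1", "MALDiv", D=D,
                             B=100_000, seed=4)
print(f"observed mean MALDiv {rand.observed_mean:.3f} "
      f"vs null center {rand.center:.3f}, p = {rand.p_two_tailed:.4g}")

table, _ = build_choice_table(events, gt, "MHC1", "MALDiv", D=D)
lrt = lrt_parametric_bootstrap(table, ModelSpec(index=True),
                               ModelSpec(index=False), n_boot=199, seed=5)
print(f"GLMM slope {lrt.full_fit.slope:.3f} "
      f"(SE {lrt.full_fit.slope_se:.3f}), bootstrap LRT p = {lrt.p_value:.4g}")
```

prints

```
observed mean MALDiv 4.730 vs null center 4.322, p = 1e-05
GLMM slope 0.442 (SE 0.074), bootstrap LRT p = 0.005
```

i.e. chosen fathers carry ≈ 0.41 more MHC-I alleles than expected under
within-pool random mating (the smallest p reportable at B = 10⁵ with the
+1 correction), and the mixed model recovers the simulated preference
slope with a bootstrap LRT p of 0.005 (smallest value at n_boot = 199).

The same analyses run from the shell: `mhcmate simulate`, `mhcmate
genotype`, `mhcmate indices`, `mhcmate infer`, `mhcmate randomize`,
`mhcmate ld`, `mhcmate run --config run.yaml`, `mhcmate validate`.

## Data formats

TSV (UTF-8, tab-separated, header row): genotypes as
`individual_id, gene, alleles` with comma-joined allele sets; choice
events as `offspring_id, mother_id, father_id, candidate_ids (semicolon-
joined), colony, conception_year`. Allele catalogs are FASTA with IDs
`GENE-k`; simulated reads are FASTA with `individual=… gene=…` tags.
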