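# Methods

## Study design

The central object is a phased haplotype panel with samples nested in
populations and populations in ancestry groups. For a given array (a set of
chromosome/position pairs), the design is leave-batch-out: samples are
randomly divided into B batches, balanced within populations (B = 10 by
default; small synthetic cohorts use B = 5); each batch is reduced to the
array∩panel "typed" scaffold and imputed with every out-of-batch sample as the
reference; batches are recombined and scored per ancestry group. The batch
construction is a single seeded round-robin whose cursor runs across
populations, which bounds both the within-population and the cohort-wide batch
size spread by one. Leakage is impossible by construction: the imputation
routine receives the batch ids and builds the reference as the set complement,
raising if the complement is empty.

## Synthetic cohorts

The generator is a founder mosaic, not a coalescent simulation. Per-site alt
allele frequencies are drawn from Beta(`sfs_shape`, 1) — a single-parameter
family whose mass concentrates at zero as the shape parameter shrinks,
emulating a rare-variant-heavy site-frequency spectrum; its mean is
`sfs_shape/(sfs_shape+1)` (default 0.2, mean alt frequency 1/6). Each
population draws its own founder haplotype pool site-by-site from the shared
frequencies (drift-like differentiation between populations), and each sample
haplotype copies founders in tracts: switch points between adjacent variants d
bases apart occur with probability 1 − exp(−`recomb_rate`·d), and each allele
flips with probability `mutation_rate` after copying.

The knobs map directly onto downstream behaviour:

- `n_founder_haplotypes` controls haplotype diversity. Adjacent-site LD from
  tract sharing scales roughly as 1/n_founders, so a 300-founder population is
  "AFR-like" (measured mean adjacent-site dosage r² ≈ 0.006 at the default
  settings) against a 30-founder "EUR-like" one (≈ 0.016).
- `recomb_rate` (per base) shortens tracts; default 2 × 10⁻⁵ gives ≈ 0.02
  switch probability per 1 kb inter-variant interval at the default variant
  density (5,000 variants on 5 Mb).
- `mutation_rate` (default 0.003) is unstructured noise that caps attainable
  imputation accuracy.

What this does **not** emulate: coalescent genealogies, recombination hotspots
and genetic-map structure, allele-frequency-dependent LD, gene conversion,
genotyping error at typed sites, indels and multiallelic sites, and sex
chromosomes. Passing tests on these cohorts therefore demonstrate correctness
of the machinery and the direction of LD/diversity/density effects — not
quantitative agreement with any real panel's coverage values.

Seeding: one master seed per configuration, children split in fixed order
(site set, then one per population), so appending a population leaves earlier
populations' draws unchanged. Positions are 1-based as in VCF; all interval
logic is half-open internally. Monomorphic sites are kept in the panel and
removed only by the downstream minor-allele-copy filter.

Array design offers `maf_stratified_random` (positions weighted 10:1 toward
pooled MAF > 0.05, the common-variant GWAS backbone of commercial arrays) and
`greedy_tagging` (repeatedly pick the variant tagging the most uncovered
variants at pairwise dosage r² ≥ 0.8 within a 50-variant window; lazy-max
greedy set cover with ties to the lower index).

## Imputation model

A haploid Li–Stephens copying model: the hidden state is the reference
haplotype being copied; per inter-site interval the state stays with
probability 1 − ρ or jumps to a uniformly drawn reference haplotype
(ρ = `switch_rate`, default 0.01, uniform genetic map); at typed sites the
observed allele equals the copied allele except with probability
μ = `miscopy_rate` (default 0.002). Untyped sites have no emission.

Because the transition kernel is "stay or jump to uniform", its g-step
composition is closed-form: stay weight (1−ρ)^g plus a uniform remainder.
Forward–backward therefore runs over typed sites only, with per-site
renormalization in linear space (no log-space needed; posteriors are
scale-free), vectorized across all target haplotypes of a batch. Untyped-site
state posteriors are reconstructed exactly by interval interpolation between
the flanking forward and backward vectors, and the alt-allele posterior folds
the state posterior through the miscopy emission:
`P(alt) = μ + (1−2μ)·Σ_k γ(k)·h_k`. The per-interval work reduces to three
matrix products against the reference allele columns, which keeps a
400-sample × 5,000-variant × three-array study under two minutes on one CPU.
Working memory is bounded by chunking target haplotypes (`chunk_floats`,
an efficiency knob only — results are identical across chunk sizes, which is
tested).

Diploid genotype posteriors assume independence of the two haplotypes given
known phase: P2 = a₁a₂, P1 = a₁(1−a₂) + (1−a₁)a₂, P0 = (1−a₁)(1−a₂). No
diploid-pair HMM is attempted; this is the documented approximation. Typed
sites are then assigned probability 1 on the observed genotype — array
genotyping error is out of scope, as is pre-phasing (synthetic phase is known;
external truth panels must supply phased GT).

Degenerate inputs: an empty reference errors; a scaffold with zero typed sites
returns the state-prior posteriors with a `ZeroTypedSitesWarning`; an
`effective_states` cap thins the reference at evenly spaced indices,
deterministically. Correctness is pinned by exhaustive hidden-path enumeration
on small instances (≤ 4 sites × ≤ 4 reference haplotypes, agreement to 1e-10)
and by a monotone self-consistency property (duplicating the truth haplotype
in the reference never lowers the truth genotype's posterior).

## Accuracy metrics

Allele frequencies, the minor allele, MAF and minor-allele copy counts (mac)
are resolved **within each ancestry group**; a variant enters a group's
metrics only with mac ≥ 2 there, so bin populations differ across groups. An
alt frequency of exactly 0.5 resolves the minor allele to alt.

- Imputation r² is the squared Pearson correlation of observed and imputed
  dosage; if either vector is constant the value is 0 (an uninformatively
  imputed variant, kept so summaries stay total rather than dropping rows).
- The best-guess genotype is the posterior argmax with ties broken toward the
  smaller alt dosage, deterministically.
- MA concordance restricts to samples where observed or best-guess genotype
  carries the minor allele; if no sample qualifies the value is 1 and the row
  is flagged (`ma_conc_defined = False`) and excluded from MA-concordance
  means. With mac ≥ 2 and observed genotypes in the comparison this cannot
  occur; the convention is purely defensive. Removing only concordant
  major-homozygote pairs guarantees MA concordance ≤ genotype concordance.

Summary MAF bins are left-open/right-closed and may overlap (the standard
queries are MAF ≤ 0.01, 0.01–0.05, > 0.01, > 0.05); the headline coverage
statistic is the fraction of variants with imputation r² ≥ 0.8. Array overlap
reports use the array's unique position count as denominator, both raw and
restricted to positions with mac ≥ 2 in at least one group.

## Power model

Penetrances under "additive" mean additive relative risk: f₁ = GRR·f₀,
f₂ = (2·GRR − 1)·f₀, with f₀ fixed by the prevalence constraint
K = f₀(1−p)² + f₁·2p(1−p) + f₂p²; a `multiplicative` option (f₂ = GRR²·f₀) is
provided because the two conventions are both in circulation among GWAS power
calculators. Models with f₂ > 1 raise a named infeasibility error. The risk
allele is always the minor allele (p ≤ 0.5 enforced). Case and control allele
frequencies follow by Bayes inversion and satisfy
K·p_case + (1−K)·p_control = p to 1e-12.

The allelic 1-df χ² NCP uses the unpooled two-arm variance by default
(`p_case(1−p_case) + p_control(1−p_control)`), with a pooled option; the two
differ at O((p_case−p_control)²). Power uses the exact one-degree-of-freedom
identity — a noncentral χ²(1, λ) variate is (Z + √λ)² — giving
Φ(√λ − √c) + Φ(−√λ − √c) with c the central critical value. This closed form
is fast enough to evaluate per-variant over the full N × GRR grid, is
cross-checked against `scipy.stats.ncx2` in the tests, returns exactly α at
λ = 0, and is clamped to [α, 1] as a floating-point guard.

Imputed variants contribute at effective sample size N_eff = N·r² — the
direction in which imputation loses information; equivalently a marker with
squared correlation r² to the causal variant needs N/r² samples to match
direct observation. The identity power(N, r²) = power(N·r², 1) holds exactly
by construction, and the information-equivalence claim itself is validated
empirically: a Monte Carlo dosage score test (T = n·corr²(dosage, status),
noise calibrated so the realized dosage-truth r² matches the target) at
N = 2500 and r² = 0.8 reproduces the analytic and simulated direct-observation
power at N = 2000 within Monte Carlo error.

Genome-wide power averages per-variant power over a MAF × r² binned summary:
MAF edges 0–0.05 by 0.005, 0.05–0.10 by 0.01, 0.10–0.50 by 0.05 (23 bins), r²
edges 0–1 by 0.05 (20 bins), each occupied bin contributing its variant-count
weight at its mean MAF and mean r². On a 10,000-variant table the binned value
stays within 0.01 of exact per-variant averaging across the whole
N = 1000–10,000 (step 50) × GRR 1.1–1.4 grid. The full-reference ceiling
forces r² = 1 for every filtered variant and reuses the same pipeline.

## Problem sizes and defaults used in the shipped analyses

The directional coverage study (tests and acceptance script) uses two
populations of 200 samples (30 vs 300 founders), 5,000 variants on 5 Mb,
`sfs_shape` 0.2, recombination 2 × 10⁻⁵ /bp, mutation 0.003, arrays of
1000/2000/3000 positions, B = 5, default HMM parameters. These sizes keep a
full three-array leave-batch-out study under about two minutes while leaving
all three metrics far from both the floor and the ceiling, where directional
comparisons are meaningful. Monte Carlo power checks use 5,000 replicates
(binomial SE ≈ 0.004 near power 0.93). The array-density grid was chosen so
that the r² ≥ 0.8 coverage fraction has imputation signal at the sparsest
array: much below 20% typed density on this cohort, no imputed variant reaches
the threshold and the statistic degenerates to the typed share.

## Known limitations

- The HMM uses constant switch and miscopy rates on a uniform map; no
  attempt is made to match any production imputation tool's parameterization
  or its info-score output.
- Haploid-independence diploid posteriors understate uncertainty when phase
  information is weak (irrelevant for the simulator, which emits true phase).
- The power model covers the 1-df allelic test under the prevalence-
  constrained GRR model only: no covariates, non-additive tests, rare-variant
  aggregation, or ascertainment beyond the prevalence model.
- Founder-mosaic cohorts have exchangeable-site LD structure; conclusions
  about specific genomic regions, rare-variant tagging, or absolute coverage
  percentages do not transfer to real panels.
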