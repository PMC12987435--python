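# Methods

## Model and assumptions

The toolkit operationalizes two premises about common disease: (i) disease
arises when an individual carries a specific *combination* of diploid
genotypes at several SNPs, and (ii) the summed population frequency of all
causal combinations approximately equals the disease prevalence P. Under
(ii), any single causal combination's joint frequency must be below P, and
a combination contributing non-negligibly should not be arbitrarily rarer
than P — hence the acceptance band `lower_factor·P < ∏F̂ᵢ < P` with strict
inequalities at both edges.

The population frequency of a genotype is not observable from a
case/control design directly; it is estimated as the prevalence-weighted
mixture of the case frequency α and control frequency β,
`F̂ = (α + λβ)/(1 + λ)` with `λ = (1−P)/P`. F̂ interpolates monotonically
from β (P→0, the population is almost all controls) to α (P→1), and the
joint estimator multiplies per-key F̂ values — an independence
approximation across the r SNPs.

## Search parameters

| parameter | default | meaning |
|---|---|---|
| `r` | 3 | combination order; the engine is generic in r, 3 keeps 3^r·C(n,r) tractable |
| `prevalence` | 0.0047 | disease prevalence as a proportion (psoriasis, Chinese Han) |
| `min_case_carriers` | 10 | minimum cases carrying the full combination |
| `lower_factor` | 0.01 | lower edge of the frequency band as a fraction of P |
| `missing_policy` | `"exclude"` | see below |

Missing calls never match a genotype key, so a sample with a missing call
can never be counted as a carrier — the conservative direction, biasing
against spurious case-exclusive patterns. Under the default policy a
missing sample is also excluded from that variant's α/β denominators
(frequencies among called samples, the standard convention); the
`carrier_only` policy keeps full cohort sizes as denominators.
Combination keys are canonicalized (sorted by variant id, then genotype
code) so no pattern is ever visited or reported twice.

The production enumerator packs per-(variant, genotype) carrier masks into
byte arrays and counts intersections with popcount, pruning on the control
side first (any control carrier disqualifies immediately). An
intentionally independent per-sample reference enumerator
(`enumerate_specific_combinations_naive`) is part of the public API and the
test suite asserts exact agreement (keys, counts and frequency products) on
randomized inputs.

## Candidate screening

The upstream QC/association screen is conventional and explicitly a
configurable stand-in: call rate ≥ 0.95, MAF ≥ 0.01, exact Hardy–Weinberg
p ≥ 1e-6 in controls, and an allelic 2×2 chi-square (no continuity
correction) with p ≤ 1e-3; a genotypic 2×3 test and a greedy r² pruner are
available by flag, both off by default. The Hardy–Weinberg exact test is a
direct enumeration of heterozygote counts in log-gamma arithmetic
(Wigginton-style); odds ratios use a Haldane 0.5 correction on zero cells.
Variants with no called genotypes are flagged undefined and can never pass
a filter.

## Background-noise thresholding

Two null scenarios: split-half controls (seeded simple randomization,
halves differing by at most one, true cases refused as input) and
off-target SNPs. Each level of collapsing takes its cutoff from its
governing scenario — genotype level from the split-half run rescaled by
`ceil(n_main/n_noise · max)`, gene level from the off-target run, whose
case cohort already is the main cohort, so its maximum passes through
unchanged. Ceiling rounding makes the cutoff conservative (it can only
rise). An empty noise run yields a maximum of 0 and is flagged rather than
raised; the derived threshold is floored at 1 so it remains a usable
carrier cutoff. Whether a published noise maximum counts carriers or
combinations is ambiguous in the field's wording; this implementation
counts **carriers** (the maximum case-carrier count among noise-run
combinations), which is the quantity the scale-up arithmetic needs.

Gene collapsing groups combinations by the sorted *multiset* of gene
symbols (two SNPs in one gene contribute a repeated symbol). A variant
annotated to several overlapping genes contributes its lexicographically
first gene by default (`multi_gene="all"` expands instead); unmapped
variants raise by default, listing every offending id. Note that
genotype-level filtering then collapsing is *not* the same operation as
collapsing then gene-level filtering — both orders are exposed, and a
regression test documents the non-identity.

## Population profiling and regression

The primary per-population frequency is the **joint carrier frequency**
(observed co-occurrence of all r genotypes); a product-of-marginals
variant is available because external panels are sometimes summarized that
way. Combinations with variants absent from the panel are skipped and
counted, mirroring real attrition when projecting exome discoveries onto a
reference panel. Mean and median summaries are always both computed; the
median is the headline (it is robust to the strong positive skew of
carrier-frequency distributions). The fit is OLS of prevalence on summary
frequency with a Pearson correlation and a 95% t-interval (df = n−2) on
the slope; prevalences are stored as proportions and reported on the
percentage scale by default (`percent_y`), the scale on which
epidemiological prevalences are quoted. Fewer than three shared
populations, or zero variance in either variable, is an error, not a
silent NaN.

## Simulator

Each test draws N populations of 15 causal genotype frequencies (groups of
4, 5, 6), computes `P = Πa + Πb + Πc` and the mean X̄ of the 34
within-group 3-genotype products, and regresses P on X̄
(`scipy.stats.linregress`); 1000 tests per condition by default. Models:

- **complete_random** — all 15·N values i.i.d. uniform(0,1).
- **constrained** — population 1 is the uniform reference; other
  populations' values are drawn uniformly within ±20% of the reference
  value. Fluctuation is implemented *multiplicatively* (value_j ∈
  [ref_j·(1−f), ref_j·(1+f)]) and clipped to the open unit interval; an
  additive reading was the alternative, but a relative band treats common
  and rare genotypes symmetrically and cannot go negative.
- **constrained_lost** — one random subset of ⌊lost_fraction·34⌋ triple
  indices is removed from X̄ in *all* populations (the loss is a property
  of the search, shared across populations), never from P.
- **constrained_lost_mixed** — additionally ⌊mixed_fraction·34⌋ fake
  triples enter X̄ (never P). A fake triple's reference value is a product
  of three fresh uniforms — matching the magnitude of a genuine 3-genotype
  product — and fluctuates per population through the same ±20% machinery.
  With both fractions zero this model is bit-for-bit the constrained model
  under a shared seed.

A degenerate test (zero variance in X̄, e.g. fluctuation = 0) is recorded
with NaN statistics and counted as non-significant — surfaced in
`n_degenerate`, never masked. Randomness is a single top-level seed from
which per-test streams are spawned (`numpy.random.SeedSequence.spawn`), so
results are reproducible and tests are independent.

Reference behaviour at 1000 tests: complete-random significance
(p < 0.05) rises with the number of populations — roughly 52% at N=10
through 100% at N=100 — while its share of strong fits (R² > 0.5) falls
from ~39% to ~7%; the constrained family holds ~98–99% significance at
N=100 with the strong-fit share stable near one half. The acceptance
script recomputes these from scratch.

## Synthetic data: what it does and does not emulate

`make_case_control` plants combinations at **exact** carrier counts:
carriers are the first `round(freq·n)` entries of a seeded permutation,
and any non-carrier that matches all keys by chance is flipped at one
variant. This makes oracle tests exact rather than probabilistic. The
background is i.i.d. binomial(2, maf) genotypes — no linkage
disequilibrium, no population structure, no Hardy–Weinberg violations
beyond the plants. Passing tests therefore demonstrate correctness of the
search and thresholding machinery, not robustness to LD or stratification,
which the toolkit's claims deliberately do not depend on. Heterozygous
keys at background MAF 0.05 give per-key F̂ ≈ 0.1 and a triple product
≈ 1e-3, inside the default prevalence band; a hom-alt key at that MAF
falls below the band, which is the expected behaviour of the estimator,
not a generator defect.

`make_panels` programs a linear frequency–prevalence relationship: the
target mean carrier frequency of each population is
`x = (prevalence − intercept)/slope` (clipped to [0,1] and flagged), every
planted combination receives carrier count `round(x·n)`, and noise is
placed where it belongs scientifically — in the *observed prevalence*
(`slope·x + intercept + Normal(0, noise_sd)`, recorded in the truth
object), since epidemiological prevalence estimates are themselves noisy
while panel genotype frequencies are measured exactly. This keeps the
regression a textbook fixed-x error-in-y fit, so the 95% slope interval
has its nominal coverage; putting the noise into x instead would introduce
an inverse-regression attenuation the estimator is not meant to absorb.

## Problem sizes and numerical choices

The test suite and acceptance script run the search on matrices of up to
~60 samples × 12 variants (where the naive oracle is exact and fast),
null-calibration over 200 seeds at 50+50 samples × 15 SNPs, panel recovery
over 200 seeds at 9 populations × 300 samples, and the simulator at 1000
tests per condition — sizes chosen so every check is exhaustive or
statistically well-powered at desk scale. Exact integer arithmetic is used
for pattern counts (`3^r·C(n,r)` via `math.comb`), frequencies are plain
double precision, and combination tables serialize floats via `repr` for
lossless round trips. Ties in output ordering are broken
lexicographically by combination key so results are identical across runs
and platforms.

## Known limitations

- The joint F̂ product assumes independence across the r SNPs; in tight LD
  it overestimates rarity constraints.
- No per-combination significance is assigned — specificity rests entirely
  on the empirical noise threshold.
- Single-process enumeration only; `r` beyond 4–5 over hundreds of
  candidates becomes expensive (the pattern count grows as `3^r·C(n,r)`).
- The QC/association defaults are stand-ins, not reconstructions of any
  particular study's unpublished criteria.
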