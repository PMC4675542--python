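# Methods

## Data model

Subjects are rows, biallelic loci columns. Genotypes are unordered allele
pairs canonicalized alphabetically ("TC" ≡ "CT"); `NN`/`--` mark missing
calls, and missing data are excluded *pairwise* — each 2×2 or 2×2×2 table is
built from the subjects complete for exactly the loci it involves, so
per-marker denominators may differ, as they do in real per-SNP frequency
tables. The unit of association is the **carriage pattern**: a conjunction of
per-locus elements, each either dominant carriage of an allele (≥1 copy) or a
recessive homozygote. A biallelic locus therefore contributes four testable
elements (two dominant, two recessive).

## 2×2 statistics

Fisher's exact p is two-sided by probability-mass ordering over the
hypergeometric distribution of the carrier-case cell given the table margins
(the `fisher.test`/SciPy convention), computed via log-gamma with a relative
tie tolerance of 1e-9; the implementation is validated against an
exact-rational enumeration oracle and against SciPy in the test suite. The
odds ratio is the cross-product ratio with the Woolf (log-Wald) interval,
exp(ln OR ± z·√Σ1/n); when any cell is zero the Haldane–Anscombe 0.5 is added
to all four cells and the result flagged. The two-sidedness and CI method are
stated defaults rather than universal conventions, and both reproduce
published-style intervals to within one unit in the last printed digit.

Hardy–Weinberg testing defaults to the exact conditional test (heterozygote
count given allele counts; p = Σ of outcomes no more likely than observed),
with a 1-df χ² alternative. Violating loci are flagged, not auto-removed: in
panels of this kind a deviation in one group only is sometimes retained on
substantive grounds, so exclusion is a policy switch (`hwe_policy`), default
`flag`, threshold p > 0.01.

Pairwise LD uses EM over the double-heterozygote phase ambiguity, started at
linkage equilibrium and stopped at a log-likelihood change < 1e-10 (≤1000
iterations). D′ = D/D_max with the sign-appropriate bound; LOD is the log10
likelihood ratio of the EM optimum against independence, with LOD > 2
labelled "moderate" linkage and anything below "weak".

## Combination mining and the permutation null

With ≤ a few dozen SNPs and order ≤ 3 the conjunction space is tiny, so the
search is **bounded exhaustive** (deterministic lexicographic order) rather
than a stochastic sampler; the reported statistics are unchanged in kind.
Two reporting conventions are enforced:

- **Minimality**: a multi-element combination is kept only if its p_f is
  *strictly* smaller than that of every sub-pattern obtained by dropping one
  element; ties lose. Order-1 records always pass.
- **Permutation adjustment**: phenotype labels are shuffled preserving group
  totals; per shuffle the entire enumerate-and-score run is repeated and the
  minimum p_f recorded; p_perm = (1 + #{min-p ≤ observed p_f}) / (1 + R).
  The min-p (family-wise) null is the conservative reading of "same result
  from randomized data of the same dimension" and mirrors re-running the
  whole search per permutation; a per-pattern scope is available as an
  option. R defaults to 100. With R = 0 the add-one estimator gives
  p_perm = 1 everywhere, never 0.

Carriage does not depend on phenotype, so each pattern's carrier column is
precomputed once and only the carrier-case cell changes across permutations;
Fisher p-values are memoized on the exact table margins. This makes
hundreds of permutations over hundreds of patterns take seconds.

Significance gates default to p_f < 0.01, p_perm < 0.05, and a 95% CI
excluding 1 — all configurable.

## SF + FLINT

The epistasis substrate is the 2×2×2 table n[a][b][y] cross-tabulating
carriage of factor A, carriage of factor B, and outcome. The procedure
accepts *any* two binary indicators (gene×sex runs on the same code path).

**Synergy factor.** With the double-non-carrier stratum as baseline,
OR_ab = odds(case|a,b)/odds(case|0,0) and SF = OR_11/(OR_10·OR_01).
Under the independent-Poisson-cells model var(ln SF) = Σ over all 8 cells of
1/n, giving exp(ln SF ± z·SE) as the CI. Any zero cell triggers a 0.5
correction applied to **all eight** cells (not only the zero ones), keeping
the variance formula defined and the A↔B symmetry exact; corrected results
are flagged. SF = 1 exactly on multiplicative tables with the correction off.

**FLINT.** Conditioning on all three two-way margins (A×B, A×Y, B×Y) leaves
a one-parameter family in x = n[1][1][1]: each cell moves by ±(x − x_obs)
according to index parity. Feasible x keep all 8 cells non-negative; the
null mass is P(x) ∝ Π_cells 1/n_cell!, computed in log space via log-gamma
and normalized. The two-sided p sums masses ≤ the observed mass with a
multiplicative tie tolerance of 1e-12 (probability ordering, mirroring the
Fisher-like construction; the literature does not pin down the tail rule, and
mid-p is off by default). A singleton support yields p = 1. The test is
invariant under all six permutations of the three variable roles, and agrees
with a brute-force all-tables enumeration oracle to 1e-10 on small totals.

**Decision.** An interaction is called only when *both* statistics agree:
synergistic iff the SF CI lies above 1 and p_FLINT < 0.05, compensatory iff
the CI lies below 1 with the same FLINT gate, otherwise none. The
conjunction of two tests is deliberately conservative; its empirical type-I
rate at n = 325/185 is well below the nominal 0.05 (the acceptance suite
measures ≈0.01).

## Composite model

Markers enter as 0/1 carriage indicators, never dosages — a combination
marker is 1 iff the subject carries every constituent element. The fit is
maximum-likelihood logistic regression (statsmodels) with per-coefficient
Wald p; for a lone binary marker the fitted coefficient equals ln OR of its
2×2 table exactly, a saturated-model identity the tests assert to 1e-8.
Complete separation is a hard error by default, with an optional weakly
ridge-penalized fallback (λ = 1e-4, flagged). ROC curves come from a
threshold sweep; the trapezoidal AUC equals the Mann–Whitney statistic
U/(n₁n₀) exactly, ties included. Transfer to a replication cohort reuses
the trained coefficients verbatim and recomputes only the ROC. Gender
moderation fits outcome ~ marker + sex + marker×sex and reports the
interaction Wald p alongside the SF+FLINT verdict on the
(marker, male, outcome) table.

## Synthetic cohorts

The generator emulates what a candidate-gene case-control panel is assumed
to be: genotypes in Hardy–Weinberg proportions (LD pairs drawn as haplotype
pairs at a planted |D′|, risk alleles in coupling), disease by a logistic
model on carriage indicators,

    logit P(case) = β₀ + Σ βⱼxⱼ + Σ γ·x_a·x_b + β_sex·male + interactions,

and exact case/control quotas by rejection sampling from the population
model (bounded at 60 vectorized batches; an unattainable prevalence errors
out). β₀ defaults to the value solving a target prevalence of 0.1 by exact
summation over the carriage strata. Planted truths are *conditional* odds
ratios, so SF_true = e^γ exactly and each marker's conditional OR is e^β;
marginal (collapsed) ORs are derived quantities computed by the same exact
stratum summation and used as recovery oracles.

The default study conditions (`paper_like_config`) are three main-effect
markers with control carriage ≈ 0.32 (recessive), 0.38 (dominant) and 0.04
(recessive) and conditional ORs 1.84, 1.80, 2.93; one epistatic
dominant-carriage pair with carriage ≈ 0.72 and 0.07 (joint ≈ 0.05), weak
mains (OR 1.1) and γ = ln 5; groups of 325 cases / 185 controls; a male
excess of ln 2.5; no missingness. Population allele frequencies are mapped
directly from the target control carriage (c = f² or 1 − (1 − f)²);
ascertainment at prevalence 0.1 shifts control carriage at most ≈0.013 below
the target, within the ±0.02 the tests allow, so no inverse correction is
applied.

What the generator does **not** emulate: population stratification,
relatedness, genotyping error beyond uniform missingness, LD blocks longer
than pairs, or covariates beyond sex. Passing tests therefore certify the
statistical machinery under the stated model, not robustness of any
real-data conclusion to those complications.

## Problem sizes and numerical choices

The acceptance suite uses 1000 simulated cohorts for SF CI coverage and for
type-I calibration, 500 per power point, 200 replicates × 200 permutations
for family-wise permutation calibration, and 200 cohorts for the composite
AUC band; the standalone acceptance script scales some of these down
(400/500/300/100×100/100) as its defaults. Exact-test tail sums use
relative tie tolerances (1e-9 for 2×2, 1e-12 for FLINT) so that analytically
tied masses land in the tail despite floating point. All factorials are
log-gamma; log-weight vectors are max-shifted before exponentiation.

## Known limitations

- Fisher and FLINT p-values are conditional exact tests and hence
  conservative on small tables; the combined SF+FLINT call inherits and
  compounds this conservatism (by design).
- The Woolf SF/OR intervals are asymptotic; with the all-cells 0.5
  correction they are defined but anti-conservative for very sparse tables.
- The minimality filter compares p-values, not effect sizes; with heavy LD
  between loci it can keep near-duplicate combinations that tag the same
  signal.
- The permutation null shuffles phenotype only, so it conditions on the
  observed genotype matrix (including its LD); this is the intended design.
- PED/MAP and VCF readers cover only the biallelic-SNP, GT-only subset
  needed for this pipeline.
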