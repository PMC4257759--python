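# Methods

This note records the statistical model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data validation
does and does not establish.

## Outcome model

The outcome is self-reported asthma age-of-onset in years, restricted to
onset at or after age two so that the early-life (first two years)
exposures precede the outcome; subjects below that floor are excluded at
load time and counted in the log.

Onset distributions are strongly right-skewed with heavy integer-year
ties, so all regression stages operate on a **rank-based inverse normal
transform**

    z_i = Φ⁻¹( (r_i − c) / (m + 1 − 2c) ),   c = 3/8 (Blom),

with average ranks for ties and `m` the non-missing count. The offset
variant is not identifiable from the analysis being reproduced; Blom is
the standard epidemiology/genetics default and the offset is exposed as a
parameter. Ties receive average ranks (so equal years map to equal
scores); this too is exposed. The transform output has mean ~0 and, absent
ties, variance within 1% of 1 for n ≥ 100; ties shrink the variance
slightly (a cohort of integer years gives ≈ 0.96), which is immaterial
because every downstream statistic is scale-free.

`z` is then residualized on an intercept, a male indicator and a study-2
indicator by OLS. Downstream tests use the residual rather than refitting
sex and study inside each exposure model; with near-orthogonal covariates
the two differ negligibly, and the residual approach is what the pipeline
standardizes on. A covariate that is constant in the sample (single-sex
cohort) is dropped with a warning instead of producing a singular fit.

## Exposure-wide scan

One simple OLS per exposure on the subjects jointly non-missing for
outcome and that exposure (**pairwise deletion** — per-item sample sizes
legitimately range from tens to the full cohort because eight items were
only asked in the second study wave). Binary items are coded 0/1;
quantitative items (cigarettes per day, breastfeeding duration) enter
untransformed. The reported statistic is the slope t with n−2 df; sign
convention: positive t = later onset among the exposed. A minimum
analyzable n of 10 guards degenerate fixtures only. For a binary exposure
the slope t-test is algebraically the pooled two-sample t-test; the test
suite checks this identity to 1e-10.

A perfect fit (exposure numerically identical to the outcome) would give
an infinite t; it is capped at 1e6 with a warning and p reported as 0.

## min-P permutation correction

Family-wise correction over a battery of K tests sharing one outcome:

1. permute the outcome vector across **all** subjects;
2. recompute every test on its own non-missing subset;
3. record the minimum p across the battery (`P_min`);
4. repeat `n_perm` times (default 10,000);
5. `p_corrected = #{P_min ≤ p_uncorrected} / n_perm`, floored at
   `1/n_perm`.

Permuting first and subsetting second preserves the battery's correlation
structure: duplicated tests incur no multiplicity penalty, independent
tests approach the Šidák bound (both verified by tests). The permuted
quantity is by default the sex/study-adjusted **residual**, which keeps
the covariate structure exactly under the null; a `permute="raw"` option
instead permutes the transformed onset and re-residualizes on the fixed
design inside every replicate (the two schemes agree closely in practice —
also under test). One RNG seeded once generates permutation r for
replicate r, so corrected values are independent of battery composition
and evaluation order, and bit-reproducible given the seed. A test failing
on more than 10% of replicates aborts the correction with a diagnostic.

The engine is shared verbatim by the 17-exposure scan and the SNP×exposure
battery. Analytic Šidák correction is provided only as a cross-check
utility.

## Dichotomized analyses

Early childhood onset is `2 ≤ onset < 6` years; later onset is `≥ 6`. The
"<6" convention resolves the boundary ambiguity of "between two and six"
in favour of the descriptive definition used for the cohort's early-onset
share. 2×2 machinery: OR = ad/bc; Woolf SE of log OR = √(1/a+1/b+1/c+1/d);
95% CI = exp(log OR ± 1.96·SE); 1-df chi-square **without** Yates
continuity correction by default (cell counts are large in the intended
use; a flag enables it). A zero cell triggers the Haldane–Anscombe +0.5 on
all cells for OR/SE/CI only (flagged in the result); a zero margin is a
degenerate-input error. The bivariate (pair) analysis keeps only
both-present and both-absent subjects, isolating the combined exposure.

## Effect modification

Sex/study-specific effects: `z ~ exposure + stratum + exposure:stratum` on
the transformed onset *before* adjustment for the stratifier under test
(adjusting first would absorb the main effect being decomposed); the
product-term t (n−4 df) and per-stratum simple slopes are reported.

G×E: `residual ~ exposure + dosage + exposure:dosage` with additive 0/1/2
minor-allele dosage coding; main effects always accompany the product term
(standard interaction-model hierarchy). Pairs need ≥ 30 jointly complete
subjects and a polymorphic SNP; skipped pairs are logged, and >10% skips
raise a warning. The correction permutes the outcome residual, not the
genotypes — the same engine and scheme as the main scan. Under a permuted
outcome the interaction t matches Student t(n−4) (goodness-of-fit under
test at n = 318).

## Synthetic cohort generator

The generator is the validation substrate; its defaults encode the study
conditions the pipeline is meant to face:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 1085 | target cohort size |
| study2_fraction / female_fraction | 0.37 / 0.61 | cohort composition |
| onset_location / onset_scale | 2.58 / 1.065 (log-years) | calibrated so onset mean ≈ 14, median ≈ 9–10, ~30% onset < 6 |
| sex_shift | −0.751 | male medians ≈ 7 vs female ≈ 11–12 years |
| study_shift | −0.436 | early-onset share ≈ 27% (study 1) vs 38% (study 2) |
| carpet↔brick coupling | log 3.2 | published exposure-pair odds ratio |
| paternal smoking coupling | log OR 3.0 | strong but unquantified in the source; placeholder |
| planted effects | carpet −0.28, brick −0.21, chest illness −0.48, father smoker −0.07, direct paternal +0.48 (conditional) | chosen so the implied *marginal* transformed-scale slopes are −0.34, −0.28, −0.48, +0.21, +0.44, back-computed from the published t-statistics |
| atopy base rate / coupling | 0.81 / log 1.8 to carpet | published marginal rate and carpet–atopy OR |
| genotyped / atopy-observed fractions | 318/1085, 402/1085 | clinical-subset sizes |
| missing_rate | 0.02 | per-item missingness beyond the structural pattern |
| snp_mafs | 26 values spread over (0.05, 0.5] | synthetic; no published frequencies |

Prevalences for the five planted exposures derive from published
early/late frequency columns; the remaining prevalences are plausible
placeholders with no published source.

Onset is a truncated log-normal on [2, 72] years (drawn by inverse CDF,
one uniform per subject), rounded to whole years by default to reproduce
realistic tie structure. **Planted effects act on the inverse-normal
latent scale**: the normal scores of the base onsets are shifted by
`Σβ·x + Σγ·x·g` and the same onset values are re-assigned by the perturbed
ranks. This leaves the marginal onset distribution untouched and delivers
the planted effect on exactly the scale the pipeline tests, shrunk only by
the overall variance inflation `√(1 + var(effects))` (~4% at the
defaults). A naive alternative — adding effects to the log-mean before
exponentiation — attenuates effects by ~30% through the truncation and
back-transform, which is why it is not used.

Correlated binary pairs come from an exact 2×2 joint distribution solved
in closed form (Plackett): given marginals and a target log OR, the
both-exposed cell solves a quadratic, so the configured association holds
exactly in expectation rather than approximately via rejection sampling.
Each exposure may appear in at most one pair.

**What the generator does not emulate:** recall bias in retrospective
questionnaires, family/twin correlation (subjects are independent),
linkage disequilibrium between SNPs, informative (non-random) missingness,
and exposure–exposure correlation beyond the configured pairs. Passing
tests therefore demonstrate correctness and calibration of the *methods*
under the modelled structure, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`/QR; battery tests use the
  Frisch–Waugh–Lovell projection so 10⁴ permutations cost one matrix
  product per chunk per test.
- Permutations are generated in chunks (default 512 replicates) to bound
  memory at ~n_chunk × n doubles.
- Corrected p-values are floored at 1/n_perm (a corrected p of exactly 0
  is not reportable from a finite permutation sample).
- Degenerate inputs (constant exposure, all-missing column, zero margin,
  single stratum, monomorphic SNP) raise typed errors at the operation
  level and are skipped-with-log at the scan level, so one bad item never
  aborts a scan.
- Missing values are NaN internally, `NA`/empty in files; subject order
  never affects results (under test).

## Validation problem sizes

The automated suite validates calibration at reduced but still
informative sizes chosen to keep the full run fast: family-wise error of
the exposure-scan correction over 500 null replicates (n = 1000,
n_perm = 1000), the G×E battery over 200 replicates (n = 318,
n_perm = 1000), planted-effect recovery over 100 seeds at n = 1085
(n_perm = 2000), Šidák convergence at n_perm = 20,000, and contingency
closed forms against brute-force recomputation on 1000 random tables.
The acceptance script reruns the same experiments at further reduced
replicate counts; all quantities it prints are computed at run time.

## Known limitations

- The recovery experiment at planted |effect| = 0.25 sits essentially on
  the min-P detection boundary at n = 1085 (analytic per-effect power
  ≈ 0.88–0.91), so its measured rate hovers around 90% by construction.
- Quantitative exposure items are analyzed as continuous regressors; an
  ordered-categorical treatment is not implemented.
- The permutation engine assumes exchangeability of the adjusted residuals
  across subjects; with strong heteroscedasticity across strata the
  `permute="raw"` scheme is the safer choice.
- Secondary stages default to exposures passing corrected significance
  (screen-then-characterize); `secondary_all` forces all exposures but the
  outputs are then exploratory.
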