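# Methods

## The estimand and the data model

All computations start from per-SNP summary associations of two traits in
non-overlapping samples: exposure effects β̂_Xj with standard errors σ_Xj
(SD units of an inverse-rank-normalized protein level per effect allele)
and outcome effects β̂_Yj with σ_Yj (log-odds for binary endpoints). Under
the instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction), each variant yields a Wald ratio
θ̂_j = β̂_Yj/β̂_Xj for the causal effect θ of a 1-SD exposure change, with
first-order SE σ_Yj/|β̂_Xj|. Effects are reported as OR = e^θ with 95% CI
e^(θ ± 1.959964·se).

## Instrument QC

The QC chain runs in this order: p < `p_instrument` (default 5e-8) →
greedy LD clumping → offline exclusion list → allele harmonization →
weak-instrument filter.

**Clumping** is PLINK-style: sort candidates by ascending p (ties broken
lexicographically by rsID, making the output independent of input order),
keep the best remaining SNP, discard every remaining SNP with r² ≥
`clump_r2` (default 0.001) against it that lies within `clump_window_kb`
(default 10,000 kb) when positions are known; without positions r² alone
decides. LD comes from a precomputed pairwise r² table, not genotypes;
absent pairs count as unlinked (r² = 0) and are tallied in debug logs.

**Harmonization** joins on rsID only. A swapped allele pair (effect↔other)
negates the outcome beta and complements its EAF; differing allele sets are
dropped as non-concordant. Palindromic SNPs (A/T, C/G) are removed under
the default `strict_remove` policy — strand complementation is never
inferred. An optional `maf_infer` policy retains a palindrome when both
traits' EAFs sit on the same side of 0.5 and outside
[`maf_threshold`, 1 − `maf_threshold`] (default threshold 0.42); frequency
agreement then orients the SNP. Outcome-side EAF is optional throughout;
exposure-side EAF is needed for F statistics and Steiger.

**Instrument strength** uses R²_j = 2·EAF_j(1−EAF_j)·β̂²_Xj and
F_j = R²_j(N−2)/(1−R²_j); SNPs with F < `f_min` (default 10) are dropped.
When the exposure EAF is missing, the fallback F_j = (β̂_Xj/σ_Xj)² is used
and flagged — this keeps EAF-less traits usable as exposures in reverse-MR
runs.

## Estimators

- **IVW**: θ̂ = Σw_jθ̂_j/Σw_j with w_j = β̂²_Xj/σ²_Yj (equivalently
  weighted regression through the origin). Fixed-effect SE = (Σw_j)^(−1/2);
  the primary multiplicative random-effects (MRE) model multiplies it by
  √max(1, Q/(J−1)), so heterogeneity widens but never narrows intervals.
  Normal reference.
- **MR-Egger**: WLS of β̂_Yj on β̂_Xj with intercept, weights 1/σ²_Yj,
  after orienting each SNP so β̂_Xj ≥ 0 (required for the intercept to be
  identified). The slope estimates θ under InSIDE; the intercept estimates
  the mean directional pleiotropic effect. SEs carry a multiplicative
  overdispersion scale floored at 1; inference uses t(J−2). The regression
  itself is delegated to statsmodels WLS; the floor and orientation are
  applied on top.
- **Weighted median**: order ratios ascending, form normalized
  inverse-variance weights w′, and interpolate the ratios at the cumulative
  midpoint s_j = Σ_{k≤j} w′_k − w′_j/2 = 0.5. Consistent while valid
  instruments hold >50% of the weight. The SE is a seeded parametric
  bootstrap (default 1,000 draws) resampling both sides' betas from their
  normal errors; the penalized-weights variant is deliberately not
  implemented. `n_boot=0` returns the point estimate alone (SE = NaN) for
  simulation studies.
- **Maximum likelihood**: β̂_Xj ~ N(γ_j, σ²_Xj), β̂_Yj ~ N(θγ_j, σ²_Yj),
  independent across SNPs and samples. The γ_j are profiled out in closed
  form, leaving −2·loglik(θ) = Σ(β̂_Yj − θβ̂_Xj)²/(σ²_Yj + θ²σ²_Xj); θ̂
  is found by bounded scalar minimization bracketed around the IVW
  estimate, and its SE from the numerical curvature of the profile
  log-likelihood. This is the one estimator here that models exposure-side
  measurement error, and it is correspondingly the least attenuated under
  weak instruments. No sample-overlap correlation parameter is included —
  the two-sample design assumes disjoint cohorts.

p-values are two-sided: normal for Wald/IVW/weighted-median/ML, t(J−2) for
Egger.

## Sensitivity diagnostics

**Cochran's Q** = Σw_j(θ̂_j − θ̂_IVW)² on J−1 df is computed once and
shared with the MRE scale (single source of truth). Exactly χ²(J−1) under
a homogeneous null; with a nonzero causal effect, exposure-side noise adds
ratio-level dispersion of order θ²σ²_Xj/σ²_Yj per SNP, so large instrument
counts against very large outcome GWAS inflate Q even without pleiotropy —
heterogeneity flags in that regime are expected, which is why the MRE model
is primary rather than a reason to discard pairs.

**Steiger directionality** sums per-SNP variance explained on each side:
2·EAF(1−EAF)β² on the standardized scale; for binary outcomes the log-odds
betas are converted with the liability-scale approximation
R² ≈ v/(v + π²/3), v = 2·EAF(1−EAF)β², with effective
N = 4/(1/cases + 1/controls). The direction is "correct" iff
R²_exposure > R²_outcome strictly (ties are conservatively not correct);
the p-value compares the implied correlations √R² by an independent-sample
Fisher-z test, matching the two-sample design (the cohorts share no
individuals, so a dependent-correlation correction has nothing to
correct). Steiger is reported per exposure-outcome pair, aggregated over
SNPs, not as a per-SNP filter.

## Meta-analysis and multiplicity

Per-cohort IVW-MRE estimates are pooled fixed-effects
(w = 1/se²); Q_meta and I² = max(0, (Q−df)/Q) quantify cross-cohort
heterogeneity, and I² > 30% switches to DerSimonian–Laird random effects
with τ² = max(0, (Q−df)/(Σw − Σw²/Σw)) and weights 1/(se² + τ²). With two
cohorts I² sits on 1 df and is volatile; this is documented behaviour, not
adjusted away. Significance uses a Bonferroni ladder with an explicit
family size m (never inferred from the data at hand): "bonferroni"
(p < α/m), "nominal" (α/m ≤ p < α), "ns". FDR control is out of scope.

## The synthetic generator

`SimConfig` draws MAF ~ U(0.05, 0.5); true exposure effects
γ_j = √(r²/(2·MAF(1−MAF))) sized to a per-SNP variance explained
(default 0.005, i.e. F ≈ 75 at the default exposure N); pleiotropic direct
effects α_j ~ N(μ, σ²) for an `prop_invalid` subset, drawn independently
of γ so InSIDE holds by construction; outcome effects Γ_j = θγ_j + α_j
(roles swap under `reverse_causal`). Observed betas add N(0, se²) noise
with se = 1/√(2·N·MAF(1−MAF)); defaults N_exp = 14,824 (a large
protein-GWAS meta-analysis) and N_out = 898,130 (a large T2D case-control
meta-analysis). Binary outcomes are emulated directly on the log-odds
scale — no individual-level liability simulation — which keeps generation
desk-scale at the cost of ignoring case-control ascertainment subtleties.

Two conventions matter for interpretation. First, the effect allele is
defined as the exposure-increasing allele, so true γ_j > 0; this is a
relabelling without loss of generality and is what makes "directional"
pleiotropy directional after Egger's β_X ≥ 0 orientation. Second, EAFs are
identical in both cohorts (one population, no frequency drift), so
`maf_infer` harmonization is cleaner here than in real cross-cohort data.

The scenario bank (`null`, `causal`, `directional_pleiotropy`,
`balanced_pleiotropy`, `forty_invalid`, `reverse_causal`) fixes the study
conditions used by the property tests and the reproduction script: 100
SNPs, θ = 0.15 where causal, pleiotropy mean 0.05 where directional. What
passing these tests shows is that the algorithms are implemented correctly
and behave as the theory predicts under their own assumptions; it does not
show that real pQTL instruments satisfy exclusion restriction, that real
LD structure is block-diagonal, or that real effect-size distributions
match the generator's.

## Numerical choices and degenerate inputs

- Clumping ties on p break lexicographically by rsID; output order is
  p-sorted; the whole pipeline is order-independent and, given a seed,
  byte-reproducible (per-pair bootstrap seeds derive from
  SeedSequence(config seed, crc32 of the pair's names)).
- J < 2 makes a pair "not estimable"; Egger and the weighted median are
  omitted (not errored) at J < 3 inside the pipeline but raise when called
  directly.
- Zero exposure betas drop the SNP from ratio-based estimators with a
  warning; se = 0 yields a degenerate CI rather than a division error.
- The MRE and Egger dispersion scales are floored at 1 so homogeneous data
  keep their analytic SEs.
- Steiger caps total R² just below 1 before atanh.
- The ML optimizer errors (rather than silently returning) on
  non-convergence or a boundary solution.

## Known limitations

- IVW (and Egger more so) are attenuated by exposure-side measurement
  error by a factor ≈ F̄/(F̄+1); at the generator's default instrument
  strength (F ≈ 75) this is a ~1.3% relative bias, visible in the
  reproduction script's recovery study. The ML estimator is the in-package
  remedy.
- No strand inference, proxy-SNP lookup, liftover, multi-allelic support,
  MR-PRESSO, mode-based or multivariable estimators.
- The exclusion list stands in for an online confounder-lookup service and
  is entirely user-supplied.
- LD is consumed as pairwise r²; the package never computes it from a
  reference panel.
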