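# Methods

`circadiff` analyzes differential circadian rhythmicity between two
conditions — here labelled `young` and `old` after its motivating use case,
comparing gene expression in cultured fibroblasts synchronized with serum
from young versus old donors, and wearable-derived physiology between young
and old subjects. This note records the models, the estimators, the
numerical choices, and what the synthetic benchmark does and does not show.

## Cosinor model

A single series sampled at hours `t` is modelled with a fixed-period
single-component cosinor,

    y(t) = M + A cos(ω (t − φ)) + ε,   ω = 2π/τ,  τ = 24 h by default,

with MESOR `M` (rhythm-adjusted mean), amplitude `A ≥ 0` (half the
peak-to-trough extent) and acrophase `φ` (peak hour, reported on `[0, τ)`).
The model is linear in the basis `{1, cos ωt, sin ωt}`; `cosinor_fit`
estimates `(M, β, γ)` by ordinary least squares and transforms to
`A = √(β² + γ²)`, `φ = atan2(γ, β)/ω mod τ`. Rhythmicity is the F-test of
`β = γ = 0` against the intercept-only model. Times are real-valued hours
since an arbitrary origin; shifting all times by a multiple of τ leaves the
fit unchanged, and no calendar logic exists anywhere in the package.

Degenerate inputs: fewer than 4 observations, or fewer than 3 distinct
times modulo τ, raise an error (the three coefficients are not
identifiable); a zero-variance series returns a flat fit with `A = 0` and
`p = 1` rather than failing.

## Two-group joint cosinor comparison

Per gene, with group indicator `G` (0 = young reference, 1 = old):

    y = (k + k₁G) + (α + α₁G) cos(ω (t − φ₀ − φ₁G)) + ε.

`k₁`, `α₁`, `φ₁` are the old-minus-young differences in MESOR, amplitude
and peak hour. With all six parameters free this surface is an exact
reparameterization of a six-column linear model (per-group intercept plus
per-group cos/sin), so the global least-squares solution is computed in
closed form by OLS and transformed to the rhythm parameterization. This
always converges, per-group amplitudes are nonnegative by construction, and
Wald standard errors for `k₁`, `α₁`, `φ₁` follow from the OLS covariance by
the delta method — identical to the asymptotic covariance a nonlinear
least-squares fit would report at the same optimum. Difference p-values use
the t distribution with `n − 6` df. The phase difference is computed inside
the cosine argument and wrapped to `(−τ/2, +τ/2]`; positive `φ₁` means the
old group peaks later (delay), negative means advance.

Per-group rhythmicity p-values are per-group zero-amplitude F-tests (the
joint model restricted to one group's rows is exactly that group's cosinor
fit). All five p-value families (MESOR, amplitude and phase differences;
rhythmicity in each group) are Benjamini–Hochberg adjusted across genes,
separately per family, and reported as q-values.

Since every gene shares the sample layout, the whole matrix is fit with one
shared pseudoinverse; 20,000 genes take well under a second.

Caveats that matter for interpretation: samples are treated as independent
(no random effect for serum donor), exactly as the analogous per-gene
nonlinear-regression tools do; a group whose fitted amplitude is ~0 has an
unidentified phase, and its phase-difference p is set to 1; zero-variance
genes are fitted flat, flagged, and kept so gene counts are stable.

## Four-model BIC-weight rhythm classification

Each gene is fit with four OLS models that all carry group-specific
intercepts (MESOR differences therefore never masquerade as rhythmicity
differences) and differ in which groups get cos/sin terms: both groups
(own β, γ per group), young only, old only, or neither. Under a Gaussian
likelihood, `BIC = n ln(SSE/n) + p ln n` with `p` = mean parameters + 1 for
the variance; additive constants cancel in the weights. Schwarz weights

    w_m = exp(−ΔBIC_m / 2) / Σ_j exp(−ΔBIC_j / 2)

lie in `[0, 1]` and sum to 1; a gene is assigned its arg-max class when
that weight exceeds the threshold (default 0.75), otherwise it is
UNCLASSIFIED. Genes classified young-only lose rhythmicity with age;
old-only genes gain it. The four-model set deliberately has no
shared-rhythm fifth model; the "both" model always allows group-specific
rhythm parameters. A per-model pooled variance is used (nothing is shared
across models or groups). SSE is floored at `1e-14 × max(total SS, 1)` so
that noiseless series do not produce `ln 0`; when two models tie at the
floor the BIC penalty prefers the more parsimonious one. Zero-variance
genes are assigned NEITHER with `w_neither = 1`.

## Gene categorization and subsets

For genes whose weight class is BOTH, direction calls at `q < 0.05`
(configurable): MESOR/amplitude UP or DOWN by the sign of the difference,
phase ADVANCE (`φ₁ < 0`) or DELAY (`φ₁ > 0`). Fold-change annotations:
MESOR log₂FC is `(M_old − M_young)·log₂10` — MESORs live on the
log₁₀(1 + count) scale, so their difference is a log fold change up to base
conversion — filtered at |log₂FC| > 0.25; amplitude log₂FC is
`log₂(A_old/A_young)` (amplitudes are magnitudes), filtered at 0.1. The
scale of both fold changes is a convention choice; both are surfaced as
parameters rather than asserted as canonical. Seven plain-text gene lists
are exported for external enrichment tools: decreased/increased MESOR,
phase advance/delay, loss/gain of rhythmicity, rhythmic-in-both.

## Heatmap normalization

Three rounds, for display only: (1) divide each gene's values by their mean
within each (age group × serum donor) block — the donor blocks absorb
baseline differences between sera; (2) average replicates per (group,
timepoint); (3) z-score each gene across timepoints within each group,
using the sample standard deviation (ddof = 1). Zero block means and zero
sds produce zeros and a per-gene flag. Round 3 is idempotent: re-z-scoring
the output is a no-op.

## Group statistics for wearable streams

Raw streams are aggregated into fixed bins (`aggregate_bins`, sum for
activity counts, mean for HR/RR), fit per subject with `cosinor_fit`, and
compared between groups: MESOR and amplitude by the two-sided Wilcoxon
rank-sum test (exact enumeration when there are no ties and min(n, m) ≤ 10,
tie-corrected normal approximation otherwise — the branch is recorded in
the result), and peak hours by a two-sample Kuiper test,
`V = sup(F−G) + sup(G−F)` over the pooled empirical CDFs of values reduced
modulo τ. V is rotation-invariant, which is what makes it appropriate for
circular phases where the CDF origin is arbitrary. The p-value is a
permutation estimate over `n_boot` random relabelings of the pooled sample
(default 10,000) with the continuity-corrected estimator `(b+1)/(n_boot+1)`,
which never reports p = 0 and is reproducible under a seed.

Known small-sample property: with n = m = 8 the permutation null of V is
supported on multiples of 1/8, and the achievable tail levels bracket 0.05
(≈0.094 at V = 0.75, ≈0.016 at V = 0.875), so at nominal 0.05 the test's
true size is ≈0.016 — conservative by construction, as is any exact
permutation test on a coarse statistic lattice. Power at realistic group
phase shifts (≈2 h) is nevertheless high; the synthetic benchmark measures
both.

## Synthetic-data generator

`simulate_expression` emulates the study design the analysis assumes: two
groups × 4 serum donors × 14 timepoints every 2 h from 32 to 58 h
post-synchronization (112 samples), values generated directly on the
log₁₀(1 + normalized count) scale as

    y = M_g + b_s + A_g cos(ω(t − t_peak,g)) + ε,

with per-(gene, donor) baseline offsets `b_s ~ N(0, subject_offset_sd²)`
(default sd 0.05, mimicking between-donor baseline differences; sd 0
recovers the iid model) and iid Gaussian noise (default sd 0.2). Rhythm
classes are assigned deterministically by gene index (first ⌈frac·n⌉ genes
BOTH, then YOUNG_ONLY, then OLD_ONLY, remainder NEITHER) so truth tables
are stable across seeds; randomness affects only parameters and noise.
Defaults: 10% / 10% / 5% rhythmic fractions, MESORs uniform on [1, 3]
(counts of ~10–1000), amplitudes uniform on [0.5, 1] shared across groups
for BOTH genes, peak hours uniform on [0, 24), old-minus-young MESOR shifts
`N(0, 0.1)` and phase shifts `N(0, 0.5 h)` where applicable. Counts are
never materialized; the generator works on the log scale the analysis
consumes, and the Gaussian-on-log-scale noise model is an assumption chosen
for consistency with least-squares fitting, not an empirical claim about
any particular dataset.

What passing the synthetic benchmark shows: the estimators recover planted
parameters, the difference tests are calibrated under the iid Gaussian
null, and the BIC classifier separates the four planted classes at the
stated effect sizes. What it does not show: robustness to count-specific
mean–variance structure, to donor-level random effects (calibration is
demonstrably not maintained under strong shared offsets, which is why the
calibration benchmark sets `subject_offset_sd = 0`), to missing data, or to
periods other than 24 h.

`simulate_wearable` generates binned activity-like streams per subject:
group cosine curve plus per-subject phase/level jitter plus noise, defaults
emulating wrist-actigraphy counts with the old group phase-advanced ~2 h.

## Numerical and design choices

- Phases are reported as peak hours on `[0, τ)`; signed differences are
  wrapped to `(−τ/2, +τ/2]` (exactly +τ/2 stays positive).
- Ties in the Kuiper ECDFs are handled by evaluating both CDFs after all
  equal values at each distinct pooled point; permutation comparisons use a
  1e-12 slack so lattice-equal statistics count as ties.
- BH adjustment is delegated to `statsmodels` (`fdr_bh`); the test suite
  cross-checks it against a direct step-up implementation.
- The rank-sum exact branch is delegated to `scipy.stats.mannwhitneyu`;
  the suite cross-checks full enumeration for all n, m ≤ 6. An
  all-constant pooled sample short-circuits to p = 1.
- A single pipeline seed drives everything; per-stage seeds are derived by
  hashing the stage name, all below 2³¹. Output tables carry a header with
  the package version, seed and a hash of the analysis-relevant config;
  floats are written with `%.10g`, making reruns byte-identical.
- Benchmark problem sizes (2000 genes for calibration and classification,
  500 simulations for phase recovery, 200 seeds for wearable power, 20,000
  genes for the full-scale end-to-end run) were chosen so that each check
  is statistically informative while the whole benchmark completes in
  minutes on a laptop core.

## Limitations

- No random effect for serum donor; inference is iid-conditional, like the
  per-gene regression tools this mirrors.
- Period is fixed, not estimated; series with true periods far from τ will
  look arrhythmic.
- The amplitude-difference Wald test inherits the small upward bias of
  amplitude estimates near zero (Rice bias); it cancels between groups
  under the null but not for very asymmetric amplitudes.
- The Kuiper permutation test is conservative for very small groups (see
  above).
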