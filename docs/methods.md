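# Methods

This note documents the models, procedures and numerical choices behind
`strainscan`, and what the synthetic cohorts do and do not establish about
real data.

## Synthetic cohort model

The generator emulates the data structure of a two-species yeast strain
collection (12 *S. cerevisiae* + 12 *S. paradoxus* by default) profiled on
custom multi-probe two-color arrays and phenotyped in a shaking plate reader
on two carbon sources. Every artifact is a pure function of
`(CohortConfig, seed)`; each stage (design, phenotypes, expression, probes,
curves) draws from its own child stream of the root seed, so stages can be
regenerated independently and reruns are byte-identical.

**Array design.** Each gene receives 3 or 4 probes (uniform), one of which is
the 3′-most probe `P_last` at distance `dx = 0`; the others get distinct
distances drawn without replacement from 1..`max_dx` (default 900 bp).
Each probe is printed 3 or 4 times (uniform). Probe GC/melting-temperature
selection and spatial array layout are not modeled.

**Phenotypes.** Growth rate and ethanol yield are log-normal across strains
with configured arithmetic mean and CV per condition
(`σ² = ln(1+cv²)`, `μ = ln m − σ²/2`, so the arithmetic mean and std/mean are
exact by construction). Defaults: growth-rate mean 0.45 h⁻¹ on glucose
(doubling ≈ 1.5 h, typical rich-medium growth) and 0.15 h⁻¹ on xylulose,
with CVs 0.13 and 0.29 — the low-dispersion/high-dispersion contrast between
the optimal and the non-natural sugar. Ethanol is expressed as a fraction of
the theoretical yield (0.90 ± 5 % CV on glucose, 0.50 ± 35 % CV on
xylulose). Doubling time is `ln 2 / rate` exactly. A log-normal was chosen
because all quantities must stay positive; no distributional form is imposed
by the data being emulated.

**Expression and couplings.** For each gene group and condition the group's
per-strain *mean* log2 expression is constructed as
`s = sd · (ρ·z + √(1−ρ²)·ε)`, where `z` is the standardized coupled phenotype
across strains, `ε` is independent standard normal, and
`sd = expression_noise_sd` (0.5 log2 by default). Per-gene deviations within
the group are re-centered per strain, so the realized group mean equals `s`
exactly and the expected Pearson correlation between group mean and phenotype
equals ρ (Monte-Carlo check: mean realized r over ≥200 cohorts at n = 24 is
within ±0.05 of ρ). Uncoupled groups take ρ = 0 (pure noise signal);
ungrouped genes are i.i.d. noise around per-gene baselines (uniform 6–12
log2). Default coupling: AA group vs growth rate on xylulose, ρ = −0.79.

Couplings live on *absolute* expression in the coupled condition. A
xylulose/glucose log-ratio profile therefore carries the coupling attenuated
by ≈ 1/√2, because the glucose side contributes independent group-mean noise
of equal variance. Recovery experiments and the reproduction script
accordingly measure the coupled condition's profiles; the pipeline's scan
reports both modes (below).

**Probe intensities.** Each placement's log2 intensity is
`expression − bias(dx) + probe_offset + replicate_noise`, with
`bias(dx) = bias_amplitude · dx / max(dx)` — a linear, monotone 3′ attenuation
(total 1.0 log2 by default) standing in for the reverse-transcription
fall-off; no functional form is prescribed by the emulated protocol. Probe
offsets (sd 0.25 log2) are fixed per probe across samples, replicate noise
(sd 0.10 log2) is i.i.d. per placement. Intensities are emitted linear-scale.
Dye-swap effects, background, spatial artifacts and scanner saturation are
deliberately out of scope.

**Growth curves.** Three-phase deterministic shape — lag (2 h), exponential
at the strain's true rate from inoculum OD 0.05, plateau at OD 1.5 —
sampled every 30 min over 48 h and multiplied by log-normal noise with CV
`od_noise_cv` (default 0.02). Real curves show diauxie, drift and
heteroscedastic reader noise; none of that is modeled, so the growth-fit
tests establish correctness of the estimator, not robustness to every
plate-reader pathology.

## Array normalization

Stages, in order; log base 2 throughout (the microarray convention —
"log" is otherwise base-free):

1. **Replicate medians** per (sample, probe); even counts take the midpoint.
2. **dx/dy pairs** per sample: every probe contributes
   `dy = log2 I(probe) − log2 I(P_last)` at its `dx`; `P_last` contributes
   (0, 0). Genes lacking a `dx = 0` probe in a sample are skipped with a
   warning. Pairs are pooled across all genes within a sample — a per-gene
   trend with 3–4 points is not fittable; a cross-sample pooled mode is
   available (`pool_samples=True`).
3. **Lowess trend** of dy vs dx: locally weighted linear regression
   (statsmodels), span 0.3, 3 robustifying iterations, evaluated on the
   sorted unique dx grid with linear interpolation between grid points and
   constant extrapolation beyond; the curve is anchored so the offset at
   `dx = 0` is exactly 0 (`P_last` is its own reference). Numerical guard:
   when the plain fit's median absolute residual is ~0 (noiseless data) the
   robustifying weights degenerate, so the plain (`it=0`) fit — already exact
   there — is used instead.
4. **Correction**: the fitted (negative) trend is subtracted from every
   probe's log2 intensity, i.e. the attenuation is added back; `dx = 0`
   probes are unchanged.
5. **Gene values**: median over the gene's corrected probes, per sample.
6. **Percentile normalization**, interpreted as quantile normalization to the
   mean quantile function across samples (whether a fixed external reference
   was intended is unknowable from the emulated protocol; the pooled mean
   reference is this package's choice). Missing values are rank-excluded and
   preserved; unequal non-missing counts are handled by linear interpolation
   of the reference quantile function; ties receive the mean of the reference
   values they span (as in limma's `normalizeQuantiles`). Note the ties rule
   necessarily trades exact multiset equality across columns for equal values
   within a tie group.

Log-ratios are `log2(xylulose) − log2(glucose)` per gene and strain, matched
by strain id; missingness propagates. The two channels of one array are
treated as two independent samples, since channels carry different strains
or sugars.

Verification: the full pipeline agrees with an independent loop-and-dict
re-implementation to 1e-9 on a 5-gene × 3-sample cohort; with injected bias
1.0 log2 and replicate noise 0.05 log2 the residual dy-vs-dx trend after
correction is < 10 % of the injected amplitude; per-sample recovered gene
values correlate > 0.99 with the generator's truth at default noise for
cohorts of ≥ 200 genes (below that, quantile normalization itself visibly
distorts individual columns).

## Growth fitting

The specific growth rate is the least-squares slope of ln OD vs time over
the curve's log-linear portion; doubling time is `ln 2` over the slope. The
"linear portion" has no canonical definition, so the package uses an explicit
windowing rule: among all contiguous windows of ≥ `w_min` points (default 5,
i.e. 2.5 h at 30-min sampling) with positive slope and `R² ≥ r2_min`, take
the longest, breaking ties by higher R² and then earlier start; if none
qualifies, fall back to the best `w_min`-point window and flag the fit
low-confidence. Windows are scored with prefix-sum statistics (O(n²)
exhaustive search, equal to a brute-force scan by construction and by test).

`r2_min` defaults to **0.999**: at the emulated noise level (OD CV 0.02) a
0.99 threshold lets the longest-window rule absorb lag and plateau points and
biases rates by about −7 %, whereas 0.999 keeps the Monte-Carlo mean within
±0.01 of truth with no low-confidence fallbacks (0.9995 starts rejecting
genuinely exponential windows). No blank subtraction is applied by default;
a constant `blank` can be subtracted before the log transform.

Cohort dispersion is the sample standard deviation (n−1) over the mean.

## Correlation analysis

Pearson's linear correlation with pairwise-complete deletion of missing
pairs; two-sided p-values from the t distribution with n−2 df; significance
at α = 0.01. Inputs with fewer than 3 complete pairs or zero variance are
rejected rather than silently returning NaN. The systematic scan ranks all
group profiles by |r| against a phenotype (ties broken by group name), flags
the single strongest significantly anti-correlated group, and reports a
Bonferroni column for transparency — no multiple-testing correction is
applied to the primary call, which at α = 0.01 and 10 independent groups
implies a family-wise false-positive rate of 1 − 0.99¹⁰ ≈ 9.6 %.

The pipeline's correlate stage scans both the log-ratio profiles and the
absolute xylulose profiles (mode column in `correlations.tsv`); the run
summary's top anti-correlated group is taken from the absolute mode, where
the generator's coupling is defined and the log-ratio attenuation (≈ 1/√2)
does not apply.

Per-gene pathway classification (used for the pentose phosphate pathway):
`positive`/`negative` if r exceeds ±0.3, induction `+`/`−` if the mean
log-difference exceeds ±0.2; values exactly at a threshold fall in the
neutral class (strict inequalities — the boundary convention is this
package's choice). Profile similarity to reference condition profiles is
plain pairwise-complete Pearson over shared genes. The bimodality rule
classifies a condition as RP-modulated or AA-modulated when exactly one of
the two groups' mean log-changes exceeds θ = 0.5 log2 in magnitude (θ is an
invented operating point; no numeric rule is prescribed by the behavior
being emulated).

Gene filtering: genes with data from fewer than k = 14 of the 24 strains are
omitted before group profiling, applied globally to the matrix rather than
per group.

## Reproduction protocol and problem sizes

`scripts/acceptance.py` re-estimates each headline quantity as the median
over 200 independent cohorts whose seeds derive from the script's `--seed`:
coupling recoveries use phenotype + expression generation (a 60-gene AA
group within a 400-gene genome per cohort — group-mean recovery is
independent of group and genome size because group means equal the
constructed signal exactly), and
dispersion recoveries simulate and re-fit 24 OD curves per cohort. These
sizes were chosen so the whole reproduction runs in well under a minute while
leaving Monte-Carlo error far inside the comparison tolerances.

## Known limitations

* The generator's noise structure (log-normal everywhere, linear 3′ bias,
  fixed three-phase curves) is a modeling choice, not an estimate from real
  arrays or readers; passing recovery tests demonstrates the pipeline inverts
  the generative model, not that it is optimal for any particular scanner.
* Quantile normalization to the pooled mean reference assumes most genes are
  not differentially expressed across samples; with very small gene panels
  (< ~100 genes) it measurably distorts per-sample values.
* The window rule is a surrogate for manual "linear portion" selection;
  heavily diauxic or noisy curves will return low-confidence flags rather
  than good fits.
* The scan's error control is per-test (α = 0.01); with many groups the
  family-wise rate grows accordingly — the Bonferroni column is provided for
  stricter use.
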