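# Methods

`tissueclock` implements a complete, simulation-testable version of a
tissue-specific epigenetic-clock analysis for mouse brain: two penalized
regression clocks (cerebral cortex and hippocampus) trained on CpG beta
values, age-acceleration summaries comparing a wild-type (B6) and an
Alzheimer-model (AD) strain, per-CpG factorial ANOVA for CpG selection, and
genomic feature / regulatory-domain annotation of the selected loci.

## Clock model

A clock is the linear model

    F(t) = b0 + sum_i b_i * beta_i + error,        DNAge = F^-1(b0 + sum_i b_i * beta_i)

where `beta_i` in [0, 1] is the methylated-read fraction at clock CpG *i*
and `t` the chronological age in months. `F` is a monotone calibration
transform; its default is the log-linear family used throughout the
epigenetic-clock literature,

    F(t) = ln(t + o) - ln(a + o)   for t <= a,
    F(t) = (t - a) / (a + o)       for t >  a,

logarithmic during the juvenile phase of fast methylation change, linear
afterwards, continuously differentiable at the knot `a`. Defaults are
`a = 1.5` months (weaning age, roughly the end of the fastest methylome
remodelling in mouse) and `o = 1` month (keeps the log branch finite at
birth); both are configurable, and an identity transform is available.
The underlying commercial clock this analysis pattern comes from does not
disclose its calibration function or coefficients, so the transform family
and all coefficients here are the package's own.

Coefficients are fit by elastic net (`sklearn` coordinate descent) of
`F(age)` on the beta matrix. Defaults: mixing `l1_ratio = 0.5`; penalty
strength chosen by cross-validated MSE on the transformed scale over a
50-point path (folds: `min(10, n)`, leave-one-out below 12 samples; fold
assignment seeded). Predictors are standardized to unit variance during
fitting and coefficients stored back on the beta scale, so serialized
models are scale-free. Only nonzero coefficients are kept. `EpigeneticClock`
is a scikit-learn estimator (`fit`/`predict`, `get_params`), so it composes
with sklearn model selection; `fit_clock`/`predict_dnage`/`evaluate_clock`
wrap it at the `MethylationMatrix` level.

Reported fit statistics: Pearson r and its square between predicted and
chronological age (the conventional way clock scatter fits are annotated),
plus the regression `1 - SSE/SST` variant and MAE in months. At prediction
time a missing beta at a clock CpG is imputed with that CpG's training mean
and counted in a per-sample warning — targeted bisulfite panels routinely
drop loci in individual samples, and refusing to predict would be worse
than a mean-imputed, flagged prediction.

## Age units

Ages are stored in months. Training/validation designs quoted in weeks are
converted at 4.345 weeks/month (365.25 / 12 / 7); the factor is an explicit
argument everywhere it is used because no universally agreed constant
exists and 4.0 is also common.

## Synthetic cohorts

The generator emulates a targeted bisulfite panel of 2,031 CpGs measured on
a factorial cohort (default 2 tissues x 2 strains x ages {3, 6, 12, 15}
months x 6 replicates, female; training cohorts of male B6 at 12/24/64
weeks, n = 4 per age; validation at 24/36/70/91/105 weeks). Each locus
belongs to one archetype — null, age-trending, tissue-offset, strain-offset,
or strain x age interaction — and the per-sample mean is

    mu = clamp(base + d_tissue*1[hip] + d_strain*1[AD]
               + (s_age + s_int*1[AD]) * F(age), 0.01, 0.99).

Observed values are Beta(mu*nu, (1-mu)*nu) — bounded, proportion-valued
noise whose concentration `nu` stands in for read-depth-limited sampling
error; the default `nu = 100` gives a per-CpG SD of about 0.05 at
intermediate methylation, a realistic figure for ~1,000x targeted coverage
once library and conversion noise are included. Missingness is completely
at random at per-cell rate 0.002 by default, chosen so that with 96 samples
roughly one locus in six carries at least one missing value — the scale of
loss a targeted panel shows from failed amplicons. Default archetype
counts (1,121 null / 300 age / 400 tissue / 150 strain / 60 interaction)
and effect ranges (age slopes 0.03–0.08 beta per unit transformed age,
tissue offsets 0.10–0.30, strain offsets 0.05–0.15, interaction slopes
0.04–0.08 with opposite-sign trends per strain) were set once for
testability at these sample sizes: large enough that a real effect of each
class is detectable at the pipeline's raw thresholds, small enough that
beta values stay in range. `ad_age_shift_months` advances the age entering
the trend term for AD samples only, injecting a known epigenetic-age shift.

What the generator does *not* emulate: read-count (coverage-level) data,
bisulfite-conversion error, batch or sex effects, correlated CpGs within
amplicons, non-CAR missingness, or biologically calibrated effect-size
distributions. Passing tests therefore demonstrate correctness of the
machinery and its statistical calibration under an idealized panel, not
biological fidelity of any particular effect size.

## Age acceleration

`dAge = DNAge - age` per sample. Group summaries use the sample median
(even n: mean of the central pair). The strain contrast is the
**difference of group medians** (AD minus B6), matching how a 6.7 vs 2.4
month pair of cohort medians yields a 4.3-month strain difference; the
median of pairwise differences is a different estimator and is not used.
Lifespan-fraction acceleration is `100 * median_dAge / lifespan` with
caller-supplied mean lifespans (defaults 17 months AD, 25 months B6);
the sign carries acceleration (+) vs deceleration (-). Per-timepoint strain
comparisons use Welch two-sample t tests with raw two-sided p-values (the
row count tells callers how many tests to correct for); identical constant
groups short-circuit to p = 1. Linear mixed models are deliberately not
used: the per-timepoint contrasts are the quantity of interest and the
Welch test gives them without a random-effects machinery that is not this
package's contribution.

Known source discrepancy: with medians +2.4 (cortex) and -2.1 (hippocampus)
months over a 25-month lifespan, the B6 fractions are +9.6% and -8.4%; a
published description of this analysis pattern transposes the two
percentages. The package always computes from the medians.

## Per-CpG ANOVA

Each fully observed locus (callers run `drop_missing_cpgs` first) is
analyzed by OLS factorial ANOVA with brain region, strain and age as
categorical factors, model = all main effects + all two-way interactions.
The three-way term is excluded: at 4–6 replicates per cell it would spend
residual degrees of freedom on a term the analysis never reports. Type II
sums of squares are used (for each term: the model of all terms not
containing it vs that model plus the term, F against the full-model residual
mean square) — equal to the classical balanced-design decomposition when
the design is balanced, and stable under the mild unbalance missing samples
introduce. Within a single-tissue analysis the region factor collapses to
one level and is dropped with a warning. Implementation detail: because all
loci share one design, orthonormal bases for each submodel are computed
once (SVD, rank-deficiency safe) and sums of squares obtained as quadratic
forms on the whole CpG x sample grid at once; the test suite checks this
against an explicit group-mean sums-of-squares oracle and against
`statsmodels.anova_lm(typ=2)`. p-values are raw; selection applies a plain
threshold (defaults: age 1e-4, strain 1e-5, strain x age 1e-5) with no
multiplicity correction, and the returned table carries everything needed
to apply one. Degenerate zero-variance loci report F = 0, p = 1; p-values
are clipped away from exact 0.

PCA is a per-CpG-centered SVD without variance scaling (beta values share a
scale); component signs are fixed by making each component's
largest-magnitude loading positive, so scores are reproducible run to run.
Hierarchical clustering is Euclidean/Ward via `scipy` linkage.

## Genomic annotation

All intervals are BED-convention 0-based half-open; a CpG is the length-1
interval at its 1-based position. CpG islands are input; shores are the
2 kb flanks of each island minus all island bases; promoters the <1 kb
strand-aware window ending at the TSS. A CpG overlapping several features
is reported with all classes plus a single primary class by the fixed
priority island > shore > promoter > 5'UTR > 3'UTR > CDS > exon > intron >
enhancer > intergenic (the priority is this package's construction — needed
to give each CpG exactly one slice in a distribution — and is configurable).
Regulatory domains follow the basal-plus-extension association rule: basal
= 5 kb upstream / 1 kb downstream of the TSS, extension up to 1 Mb per side
stopping at the nearest neighboring gene's basal boundary, clipped to the
chromosome. Enrichment of a CpG selection against a background panel is the
region-level binomial test: p_hit = fraction of background loci covered by
the term's domains, p = upper-tail Binomial(|selected|, p_hit) at the
observed hit count. Gene-set membership and enhancer intervals are
caller-supplied files; no ontology or genome build is bundled, and no
cross-assembly lift-over is attempted.

## Pipeline and reproducibility

`run_paper_mimic` chains simulate → fit (per tissue) → validate → predict →
accelerate → ANOVA → select → annotate, writing every intermediate TSV, a
manifest (config, master seed, per-stage sub-seeds split via
`numpy.random.SeedSequence.spawn`) and a JSON report. Identical config +
seed reproduce every output byte outside the manifest timestamp. The CLI
(`tissueclock simulate|fit|predict|accelerate|anova|select|annotate|great|run`)
is a thin layer over the library; exit code 2 flags validation errors,
1 internal ones.

## Problem sizes in the shipped checks

The acceptance script and test suite run the full 2,031-locus panel at the
study's cohort sizes (96 experiment samples, 12 training / 20 validation
samples per tissue), 2,000 null loci for type-I calibration, and 20
independent seeds for the injected-shift recovery; unit tests use reduced
panels (a few hundred loci) where the full panel adds nothing to the
property under test.

## Limitations

* The clock's cross-validated elastic net shrinks coefficients; predictions
  of cohorts outside the training age range are slope-attenuated by a few
  percent at the default noise level. The injected-shift check therefore
  compares the recovered strain difference with the shift actually encoded
  by the fitted clock (measured on the noise-free expected cohort), and
  separately verifies exact recovery of the injected shift when
  observations are noise-free.
* Raw-threshold CpG selection inherits the multiplicity behaviour of the
  original analysis style; the ANOVA table is the place to apply FDR
  control if desired.
* Beta-distributed noise makes the per-locus F tests only asymptotically
  exact; calibration is verified empirically at the default design (96
  samples) rather than guaranteed analytically.
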