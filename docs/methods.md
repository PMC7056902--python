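# Methods

## The prediction problem

The package addresses genomic prediction in a small, family-structured
population — the motivating case is an F2 broiler cross of a few hundred
birds genotyped at 10⁴–10⁵ SNPs. With many more markers than individuals,
most markers carry no information about the trait, and their noise enters
the genomic relationship matrix. The package implements a marker
preselection step (the homozygote-contrast screen, PMS), an alternative
GWAS screen, GBLUP prediction, and a leave-one-out evaluation protocol
that keeps preselection honest (the predicted bird never informs the
screen that chose the markers used to predict it).

## Data model and quality control

Genotypes are integer allele2 dosages (0/1/2) with a single missing
sentinel. QC retains markers with call rate strictly above 0.70 and MAF of
at least 0.01; the asymmetry (strict vs inclusive) mirrors the usual
phrasing "more than 70 % called" / "MAF below 0.01 deleted" and is fixed so
marker counts are reproducible. MAF uses only non-missing calls. The
MAF-spectrum summary bins minor allele frequencies into half-open
intervals (default width 0.05, final bin closed at 0.5) and reports the
coefficient of variation of bin counts (sample SD / mean) as a uniformity
measure of a panel.

Phenotypes are corrected once, on the full data, by OLS with sum-to-zero
effect coding of sex (2 levels) and batch (6 levels):
`y_c = y − sex effect − batch effect`, intercept retained so mean(y_c)
equals mean(y) in balanced designs. Sum-to-zero contrasts make "the sex
effect" a well-defined deviation; the full-data fit (rather than per-fold
refitting) reflects that fixed effects are estimated more precisely from
all records, and the correction involves no genomic information, so it
does not leak phenotype signal into genotype selection beyond the
individual's own y_c — which *is* excluded per fold.

## Marker screens

**PMS.** For each marker, over a reference subset of individuals and
ignoring missing genotypes, `d = |mean(y_c | dosage 0) − mean(y_c |
dosage 2)|`. Markers lacking either homozygote class are ineligible.
`d′ = d / max(d)` over eligible markers of the current reference subset,
so `d′ ∈ [0, 1]`; markers with `d′` strictly greater than the cutoff
(default 0.05) are retained. Normalisation is recomputed inside every
cross-validation fold because the reference subset changes; heterozygotes
never enter the contrast.

**GWAS.** Per marker, OLS of y_c on dosage with intercept; two-sided
p-value from a t distribution with n−2 degrees of freedom; markers with
zero dosage variance or fewer than 3 observations are untestable. Markers
with p strictly below α (default 0.01) are retained. No multiple-testing
correction is applied — the screen thresholds raw p-values by design,
since the goal is enrichment, not inference.

Both screens are computed from per-marker sufficient statistics
(class counts/sums; Σx, Σx², Σxy, Σy, Σy² over non-missing calls), which
makes the per-fold rescreen a rank-one downdate rather than a rescan —
algebraically identical to recomputing on the n−1 remaining individuals.

## GBLUP and REML

The model is `y = 1μ + g + e`, `g ~ N(0, G σ²_g)`, `e ~ N(0, I σ²_e)`,
with `G = MM′ / Σ 2pᵢ(1−pᵢ)` where column i of M codes genotypes as
−2pᵢ, 1−2pᵢ, 2−2pᵢ and missing genotypes are 0 after centering (the
expected score). Allele frequencies are the observed frequencies over all
genotyped individuals and are *not* recomputed per cross-validation fold:
genotypes of validation individuals are known; only their phenotypes are
withheld. Monomorphic markers contribute nothing and are dropped (or,
inside the cross-validation fast path, carried with zero weight —
identical G either way).

With a single genomic variance plus residual, the restricted likelihood
profiles down to one dimension. Writing `K(h²) = h²G_tt + (1−h²)I` with
eigendecomposition `G_tt = U D U′` computed once per fit, the REML
criterion at heritability h² is

    −2 l_R(h²) = (n−1) log σ̂²_p + log|K| + log(1′K⁻¹1) + const,

with `σ̂²_p = y′Py/(n−1)` the profiled total variance. Brent search on
h² ∈ [10⁻⁶, 1−10⁻⁶] with tolerance 10⁻⁸ gives the exact optimum (verified
against a 10⁻⁴ grid in the test suite). `σ̂²_g = ĥ²σ̂²_p`,
`σ̂²_e = (1−ĥ²)σ̂²_p`. The standard error of ĥ² is the inverse square root
of the negative numerical curvature (central second difference, step 10⁻⁴)
of the profiled restricted log-likelihood — an observed-information
approximation; other software may report differently defined SEs.
Components below 10⁻⁸ × var(y), or ĥ² within 10⁻⁵ of a bound, are flagged
as boundary estimates. Eigenvalues of K are floored at 10⁻¹² to guard
against slightly negative numerical eigenvalues of G near h² = 1.

Prediction: `μ̂` is the GLS intercept on the training block with
`V = G_tt σ²_g + I σ²_e`, and `ĝ = σ²_g G[·,t] V⁻¹ (y_t − 1μ̂)` for every
individual in G, phenotyped or not. If a Cholesky solve of V fails, a
10⁻⁶ diagonal jitter is applied once and logged. The strongest correctness
oracle is the exact equivalence to SNP-BLUP / ridge regression with
shrinkage `λ = σ²_e Σ2pᵢ(1−pᵢ) / σ²_g` on the same centered markers,
checked to 10⁻⁶ over random instances.

## Leave-one-out cross-validation

For each phenotyped individual k: (1) markers are preselected on the other
n−1 individuals only; (2) G is rebuilt on the selected subset over all
individuals; (3) variance components are re-estimated by REML on the n−1
training phenotypes (a flag can freeze them for speed; off by default);
(4) k's GEBV is predicted with its phenotype withheld. Accuracy is the
single pooled Pearson correlation of the n out-of-fold GEBVs with y_c —
with leave-one-out there is no per-fold correlation to average — and its
uncertainty is a bootstrap SE (SD of the correlation over 1,000 seeded
resamples of individuals). Unbiasedness is the OLS slope of y_c on GEBV
(1 = unbiased). A fold whose selection is empty aborts the run with a
diagnostic (configurable to skip and record the fold as failed).

Scenario comparison: individuals are resampled with replacement, jointly
for both scenarios; both accuracies are recomputed on each of 1,000
replicates; a paired t-test with n_boot − 1 degrees of freedom is applied
to the replicate differences. The bootstrapped-paired-t construction
admits variants; this one (joint resampling, t over replicate differences)
is recorded in the output metadata. All-zero differences give t = 0,
p = 1 by convention. A single master seed drives deterministic per-purpose
streams, so reruns are bit-identical.

## The simulator

The generator emulates the structure of a two-line F2 design: 6 F0 sires
from one line and 14 F0 dams from another, F1 matings, 8 half-sib F2
families (shared F1 sire), 395 F2 individuals by default. Line allele
frequencies are Beta-perturbed around a shared base frequency drawn
uniform on [0.05, 0.5] (concentration parameter `divergence`, default 10 —
moderate divergence; the real lines' divergence is unknown, so the
parameter is exposed, not calibrated). Gene dropping uses Haldane
(no-interference) recombination over 28 autosomes of 1 Morgan with
uniform marker positions; the sex chromosome is deliberately omitted
(hemizygous inheritance would complicate dosage handling without adding
evaluative power). Phenotypes are additive: QTL effects drawn N(0,1) and
rescaled so the realized genetic variance is h²·SD², residual variance set
so the realized sample heritability equals the target exactly; trait scale
defaults to a 12-week body-weight-like trait (mean 2034, SD 360,
target h² 0.703), with a ±150 sex deviation and six fixed batch
deviations (−50…+50) removed later by the correction step. Missingness is
uniform at random; constants for sequencing-like (0.051) and chip-like
(0.005) per-genotype rates are provided.

What the simulator does not emulate: genotyping error, per-marker
missingness heterogeneity, selection across generations, dominance or
epistasis, and chrZ. Passing tests therefore demonstrate correctness of
the algorithms and calibration under an idealised additive F2 — not
performance guarantees on any real dataset.

## Validation design choices

The preselection-gain experiment (PMS cutoff 0.05 vs all markers,
leave-one-out, n = 200, m = 2,000, 20 QTLs, h² = 0.3) uses unlinked
Hardy–Weinberg panels rather than the F2 generator. The reason is
mechanism, not convenience: preselection pays off when most of the panel
carries no trait information, the regime of a 10⁵-marker genome-wide
panel. A 2,000-marker F2 genome has such dense within-chromosome linkage
that nearly every marker tags a QTL, so there is almost nothing for the
screen to remove (the measured gain there is ~0.00–0.02, and it is also
reported for transparency by the acceptance script). On unlinked panels
the measured mean gain is ~0.1–0.2 with PMS winning in 8/10 replicates,
consistent in direction and magnitude with preselection gains reported for
real dense panels. Heritability-recovery and null-calibration experiments
do use the F2 generator, where linkage is the point.

Problem sizes in the test suite (e.g. n = 400 for recovery, n = 200 for
the gain experiment, 10–20 replicates) were chosen as the smallest sizes
at which the checked bounds are statistically comfortable for a routine
continuous-integration run.

## Package shape

The core fit follows the statsmodels convention — a `GBLUP` model object
constructed from data whose `fit()` returns a `GBLUPResults` carrying
estimates, uncertainties and a `summary()` — because the centrepiece is a
variance-component model fitted to data. Screens, evaluation and the
simulator are plain functions over shared containers, which matches how
they are composed in pipelines. The command-line interface is a thin layer
over the library; every run persists its resolved configuration and seed.

## Known limitations

* Single trait, single genomic variance component; no pedigree or
  single-step matrices; no dominance.
* REML SEs are information-based approximations and can be optimistic
  near the h² boundary.
* Leave-one-out with per-fold REML refits is O(n) eigendecompositions of
  (n−1)×(n−1) matrices; practical to a few thousand individuals, not
  beyond.
* The bootstrap SE of accuracy treats out-of-fold predictions as
  exchangeable across individuals, ignoring family structure in the
  resampling.
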