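# Methods

This note records the models implemented in rxbench, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices that matter for reproducing its outputs.

## Study emulated by the synthetic cohort

The package targets the design of a two-cohort anti-TNF response study: a
discovery cohort (default 2,031 training + 675 leaderboard subjects,
non-response prevalence K = 0.217) and an independent test cohort (default
591 subjects, K = 0.357), all patients with at least moderate baseline
disease activity (DAS28 > 3.2), clinical covariates (age, sex, anti-TNF
drug, methotrexate use, baseline DAS28), and common-SNP genotypes
(MAF ≥ 0.01) in Hardy–Weinberg proportions.

The generator draws, per SNP, an allele frequency uniform on the
configured MAF range and Binomial(2, p) dosages — no linkage
disequilibrium, imputation uncertainty, or population structure is
simulated, which are deliberate non-goals. Consequences: the GRM has
exactly independent markers (its off-diagonal mean is −1/(n−1) under
realized-frequency standardization), feature-selection nulls are cleaner
than in real data (a random SNP never tags a causal one), and REML
recovery results here say nothing about confounding by stratification.

**Genetic architecture.** Causal loci are sampled uniformly without
replacement and share one standardized effect size with
Σ 2p_i(1−p_i)β² = h²_liability computed on realized frequencies, the
"fixed number of loci of equal effect" architecture that the power theory
assumes. Liability is genetic score plus N(0, 1−h²) residual; labels
threshold the liability at Φ⁻¹(1−K), or at the empirical quantile when an
exact case count is wanted (the challenge layout uses exact counts, e.g.
211 = round(0.357·591) test-cohort non-responders).

**DAS28 and EULAR.** Baseline DAS28 is truncated normal(5.5, 1.2) on
(3.2, 9.4] — a plausible clinic distribution on the instrument's range;
no empirical distribution was available to fit. The EULAR table is the
standard one: improvement > 1.2 → Good if endpoint ≤ 3.2 else Moderate;
0.6 < improvement ≤ 1.2 → Moderate if endpoint ≤ 5.1 else None;
improvement ≤ 0.6 → None. Non-response means category None. Improvement
(ΔDAS28 = baseline − follow-up) is placed by inverse-CDF inside the EULAR
region dictated by the subject's label — responders in the improvement
> 1.2 region, non-responders in the ≤ 0.6 region — so re-classifying the
trajectories reproduces the labels exactly. Improvement decreases with
non-response liability (higher liability, less improvement) and carries
small fixed clinical effects (age, sex, methotrexate, drug) so that
clinical-only regressors of ΔDAS28 beat chance while classification labels
remain purely genetic + noise. Follow-up interval heterogeneity is not
modelled (no per-subject times exist to calibrate it).

## Genotype QC

Thresholds default to subject missingness > 5%, SNP missingness > 1%,
MAF < 1%, HWE χ² p < 1e-5, applied in that order with MAF/HWE computed on
post-missingness calls. Because every removal changes the denominators of
the remaining missingness fractions, the rules are swept to a fixed point;
this is what makes `apply_qc` idempotent, a property the test suite
enforces. The HWE test is the plain 1-df chi-square (not an exact test);
monomorphic SNPs count as trivially in equilibrium.

## REML heritability

Single-GRM REML only: per-SNP-subset fits are separate single-component
models, not a joint partition. The GRM is the standard HWE-standardized
estimator with mean-imputation of missing dosages and exclusion of
monomorphic markers. The restricted likelihood is profiled over
h²_obs = σ²_g/(σ²_g+σ²_e) on [0, 1] after one eigendecomposition of the
GRM: a 21-point coarse scan brackets the optimum, Brent refines it to
xatol 1e-8, and the profile optimum is verified in tests against a
0.001-step grid. Negative GRM eigenvalues are clamped at zero with a
warning; an identity GRM is flagged degenerate (h² unidentifiable). The
LRT against σ²_g = 0 uses the ½χ²₀+½χ²₁ boundary mixture, so p = 0.5 at
the boundary. Binary traits are analyzed on the observed 0/1 scale and
converted by h²_liab = h²_obs·K(1−K)/z²; no ascertainment correction is
applied because simulated study prevalence equals modelled prevalence.
Baseline DAS28 is included among REML covariates in the pipeline (it is a
configurable choice).

## Power and AUROC theory

Per-locus liability variance: genotype penetrances proportional to
(1, λ, λ²) normalized to prevalence K, each mapped to a liability mean
shift μ_g = T − Φ⁻¹(1−K_g) with unit within-genotype variance; the locus
h² is Var(μ)/(1+Var(μ)). Grid cells whose implied penetrance exceeds 1
are infeasible and skipped. Loci required: round(h²_target / locus h²),
minimum 1. Detection power: the 1-df allelic case-control chi-square with
case/control allele frequencies from the penetrance model and the
non-centrality of the two-sample frequency comparison; default sample
sizes 587 cases / 2,119 controls (a 2,706-subject cohort at K = 0.217 —
the counts are a package choice, configurable). Expected heritability
explained is the median power over the (p, λ) cells whose locus count
rounds to the stated value.

The AUROC of a score explaining liability variance v treats the
case-conditional and control-conditional score distributions as normal
with truncated-normal moments (means v·i, v·i₂; variances v − v²i(i−T)
etc.). Its algebraic inverse recovers v from an AUROC exactly, which the
tests pin to 1e-6 round-trip accuracy. Independent clinical and genetic
components combine by adding liability variances.

`min_h2_fraction_for_auroc` answers "what fraction of the heritable
component must a model explain to reach a target AUROC". By default the
genetic component is combined with an independent clinical predictor of
AUROC 0.6214 — the best clinical-covariate benchmark — because the
actionability question is about *adding* genetics to clinical practice,
not replacing it; passing `clinical_auroc=0.5` gives the purely genetic
inversion (which needs 72.6% of an h²_obs = 0.18 trait for AUROC 0.75,
versus 55% on top of the clinical baseline). Bisection reports the
smallest fraction on a 0.001 grid.

## Tie-aware scoring

A submission is scored as if every ordering consistent with its scores
were equally likely. Per ordering, the AUPR is the trapezoidal area under
the rank-by-rank (recall, precision) path anchored at (0, 0); the
tie-aware statistic is the exact expectation over orderings, computed per
tie block from hypergeometric moments in O(n log n) and verified against
exhaustive enumeration for every instance with n ≤ 8 and against Monte
Carlo shuffling at larger n. Two consequences of this convention are
worth knowing: a perfect ranking of P positives scores 1 − 1/(2P), not
exactly 1; and a fully tied prediction scores slightly above the
prevalence (0.3594 for 211 positives of 591, versus prevalence 0.3570),
converging to the prevalence as n grows. The matching AUROC expectation
is the Mann–Whitney identity with half-credit for ties: exactly 0.5 for a
fully tied prediction. Both metrics are invariant to strictly monotone
transforms of the scores. Higher score means predicted non-responder —
the rarer class must be the positive one for the AUPR floor above to
apply.

Permutation p-values use the add-one estimator (1+hits)/(n_perm+1), so
they are never zero; ranks are descending with average rank on ties, and
the overall rank is the mean of the AUPR and AUROC ranks.

## Bootstrap, null models, paired comparisons

Bootstrap rank robustness resamples subjects with replacement (default
B = 1,000), rescoring every submission per iteration; single-class
resamples are redrawn and counted. "Robustly better" = two-sided Wilcoxon
signed-rank on the paired per-iteration estimates (exact for B ≤ 25,
normal approximation with tie/zero handling otherwise) with p < 0.05 and
the median advantage in the right direction.

The random-feature null trains the same pipeline on uniformly resampled
SNP sets of matched size (default 100 draws) and reports the add-one
empirical p of the informed-feature model. Enrichment across pipelines is
the one-sided exact Kolmogorov–Smirnov D⁺ against Uniform(0,1); the
sensitivity analysis replaces each empirical p by its exact one-sided
Clopper–Pearson upper bound (Beta(hits+1, draws−hits) quantile, default
confidence 0.9987) before re-testing.

Full-vs-clinical contrasts are two-sided paired t-tests on per-team metric
differences, with per-drug subsets rescored on their own subjects and
Bonferroni correction across subsets. The pipeline's baseline "teams" are
ridge-logistic models over significance-screened SNPs (point-biserial
chi-square, α = 1e-3, capped at a per-team feature budget drawn from a
per-team random half of the genome) plus clinical covariates, against the
same model without SNPs. The screen matters: without it, noise SNPs
systematically degrade the full model out of sample and the paired test
correctly flags that degradation, which is a real difference, not a
type-I error. With screening, a heritability-free cohort admits almost no
SNPs, the team differences are genuinely null (often exactly zero, giving
the degenerate p = 1), and the rejection rate stays at or below the
nominal level — the calibration property the tests check.

## Ensemble stacking

Training meta-features are leave-one-out base predictions (row i never
predicted by a model that saw row i); test meta-features are full-refit
base predictions — the standard stacking convention, chosen where the
design was open. Normalizations: raw, z-score, scale-0–1, always with
training-set parameters applied to test columns; constant columns map to
zero with a warning. The reference meta-classifier is Naive Bayes with
per-feature, per-class Gaussian kernel densities (Silverman's rule per
feature and class by default; a fixed bandwidth override exists so tests
can pin the posterior to hand-computed kernel sums at 1e-12). Logistic,
Gaussian NB and decision-tree metas are registered alongside, with a
plug-in hook for more; the original sixteen-classifier sweep is out of
scope.

## Problem sizes used in the checked properties

All stochastic verification runs at desk scale, chosen once: REML
recovery at n = 800, M = 2,000, 25 replicates per heritability level
(0, 0.18, 0.4); power spot-checks on a 3×3 (p, λ) grid with 1,200
simulated studies per cell; AUROC formula checks on 200,000 simulated
liabilities; calibration of the paired comparison over 20 end-to-end runs
with 260-train/160-test cohorts of 240 SNPs and 5 team variants;
enrichment power at h² = 0.5 over 10 causal loci with 30 null draws per
run. The default `PipelineConfig` is likewise desk-scale; the "challenge"
preset restores the full cohort sizes and resampling depths.

## Known limitations

- No LD, stratification or imputation noise; see above for what that
  implies about external validity.
- The liability-scale conversion assumes study prevalence equals
  population prevalence (true by construction here, not in ascertained
  designs).
- The genomic-profile AUROC form treats conditional score distributions
  as normal; its error is well under 0.005 across the variance range the
  tests cover but grows for extreme K and v.
- Baseline team models are deterministic ridge fits, stand-ins chosen for
  reproducibility of the inference layer, not re-creations of any
  specific modelling pipeline.
- The Wilcoxon normal approximation is used for B > 25; exact small-B
  behaviour is available but the bootstrap default never exercises it.
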