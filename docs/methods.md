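# Methods

## The problem and the estimator

Craniodental phenotypes (cranial and dental measurements and discrete
traits) are widely used as proxies for neutral genetic variation when DNA
is unavailable. The question this package operationalises is *how much*
neutral genomic signal each of four standard data types preserves —
cranial metrics, dental metrics, cranial nonmetric traits, dental
nonmetric traits — and whether combining them helps.

The design is a D_P–D_G comparison. For a set of matched (but unpaired)
population samples we compute:

* **D_G**: pairwise Weir–Cockerham F_ST from biallelic SNP genotypes,
  estimated per locus from the method-of-moments variance components
  a (among populations), b (among individuals within populations) and
  c (within individuals), F_ST = a/(a+b+c), then averaged over the loci
  with a defined estimate for each population pair (average of per-locus
  ratios; a ratio-of-sums variant is available for sensitivity analysis).
  Monomorphic loci are excluded per pair and counted. Negative estimates
  are retained (an estimator property, not an error).
* **D_P**: pairwise Mahalanobis D² between population mean vectors,
  D²_ij = (X_i − X_j)ᵀ S⁻¹ (X_i − X_j). For metric data X are
  per-variable within-population geometric means of the size-corrected
  measurements and S is the pooled within-population covariance
  (per-population unbiased covariances weighted by n_i − 1). For
  nonmetric data X are probit thresholds Φ⁻¹(p) of binary trait
  frequencies and S is the pooled Pearson correlation of the binary
  indicators, each entry weighted by that population's pairwise
  complete-observation count. The combined craniodental D² is the
  element-wise average of the four block matrices weighted by their
  variable counts (37 + 28 + 24 + 25 = 114).
* **C / G**: climate distance (Euclidean over five temperature variables
  in raw °C — they share units; standardization is available) and
  geodesic distance (haversine, spherical Earth R = 6371 km).

The **neutrality estimate r** is the partial Pearson correlation between
the off-diagonals of D_P and D_G controlling for C (or G): both vectors
are regressed on the covariate by OLS with intercept and r is the Pearson
correlation of the residuals. This equals the closed-form single-covariate
partial correlation (tested to 1e-10).

Sampling uncertainty is quantified by three nested resampling schemes,
each run for a configurable number of iterations (1,000 by default,
smaller in the packaged runs):

1. **population** — drop one random population from every data set and
   one random individual per remaining population, independently per data
   set (samples are unpaired);
2. **variables** — additionally undersample each phenotype data type to a
   common 24 variables (the combined type draws 24 from the pooled 114
   without block quotas; a proportional option exists);
3. **loci** — additionally undersample the SNP loci to 24, exposing the
   stochastic variation of neutral evolution (a heritable neutral
   phenotype is roughly as informative as a single neutral locus).

Each distribution is summarised by its median and the 2.5th/97.5th
percentiles (linear interpolation between order statistics — stated
explicitly because percentiles on n = 1,000 are definition-sensitive).
Distributions produced under one master seed are paired: per-iteration
sub-seeds are derived counter-based from (master seed, iteration, stream),
so iteration i shares its population drop, genomic individual drops and
locus subset across data types. Pairwise repeated-measures t-tests with
Bonferroni correction (m = number of pairs) rely on this pairing and
refuse unpaired inputs. A loci draw that leaves some population pair with
no defined locus is redrawn from a fresh sub-seed (logged), keeping the
iteration count fixed.

Ordination diagnostics: 3D Kruskal nonmetric MDS minimising stress-1
= sqrt(Σ(d̂ − d)²/Σd²), with disparities d̂ from pool-adjacent-violators
isotonic regression (primary tie treatment: ties are ordered by current
configuration distance, leaving them unconstrained), optimised by SMACOF
majorization with Kruskal's disparity normalisation, best of several
random restarts plus one classical-scaling warm start. Stress below 0.15
is the conventional acceptability gate (strict inequality). Phenotype
configurations are Procrustes-superimposed onto the F_ST configuration:
centering, scaling and an orthogonal transform minimising the residual sum
of squares. Reflections are allowed because NMDS axes have arbitrary
chirality; translation is included because NMDS configurations are
translation-arbitrary.

## Preprocessing

Metric tables: individuals with strictly more than half of their
measurements missing are removed (exactly half is retained), remaining
gaps are imputed by k = 5 nearest neighbours (standardized Euclidean
distance over shared variables, scaled by the fraction of shared
variables; backed by scikit-learn's nan-Euclidean KNN imputer and verified
against an exhaustive-search oracle), and each row is divided by its
geometric mean. The size correction both removes gross size and absorbs
size-related sexual dimorphism, so no separate sex regression is applied;
male-only analyses are a configuration filter. Nonmetric tables: bilateral
scores are merged by the individual-count method (highest expression of
the available sides), graded scores are dichotomized at user-supplied
breakpoints (grade ≥ breakpoint = present), and per-population trait
frequencies carry their observation counts and pairwise counts for the
pooled correlation. Probit thresholds of frequencies exactly 0 or 1 use
the continuity adjustment p̃ = (n·p + 0.5)/(n + 1), applied only at the
boundary so that p̃ → p as n grows.

## The synthetic study

The generator emulates the study conditions end to end so the pipeline is
testable with known ground truth:

* **Geography/climate**: 26 populations along a serial path on the sphere
  (latitude drifting from −10° to 60°, longitude stepping east). Five
  temperature variables are smooth functions of latitude plus regional
  noise (sd 5 °C, the scale of continentality and altitude effects),
  giving an off-diagonal climate–geography correlation around 0.3 — the
  confound the partial correlation controls for.
* **Genotypes**: a serial-founder Balding–Nichols chain. Ancestral
  frequencies are uniform on [0.05, 0.95]; population k's frequency is a
  Beta draw around population k−1's with incremental variance set so the
  cumulative divergence follows F = 0.02 → 0.25 linearly along the path
  (human-scale pairwise F_ST). Genotypes are binomial(2, p). A star mode
  (independent draws around the ancestral frequency) exists for
  moment-oracle checks; the serial chain is the default because it yields
  divergence that accumulates with path separation, which is what the
  framework assumes. The implied coancestry is Θ_ij = F_min(i,j).
* **Phenotypes**: four blocks of 37/28/24/25 variables with default
  heritabilities 0.9/0.2/0.5/0.8 (mirroring quantitative-genetic
  expectations for cranial metric / dental metric / cranial nonmetric /
  dental nonmetric data) and a common climate effect β = 0.1 per trait.
  Per block, population trait means are built from a small number of
  genetic factors (default 3) with between-population covariance 2h²Θ,
  loading onto traits through unit-norm loadings — traits within a block
  are pleiotropically integrated while blocks are independent modules.
  The climate component uses row-orthonormal loadings so it spans the
  five climate dimensions evenly. Individuals add within-population noise
  with a random unit-variance correlation. Metric blocks are exponentiated
  onto a positive measurement scale with an individual size factor
  (slightly sex-shifted) so the size correction is exercised; nonmetric
  blocks are graded 0–3 by liability thresholds whose baseline presence
  frequencies span 0.15–0.85, with breakpoint 1 for dichotomization.
  Genomic (default 25/population) and phenotypic (default 60/population)
  individuals are independent draws — matched but unpaired samples.
  MCAR missingness (default 5%) is applied to every block.
* **Truth**: the generator records the latent population means and the
  within-block correlation per block; `true_signal_r` computes the
  realized neutral signal (partial correlation of the latent-mean D² with
  the realized F_ST) as a per-seed ground truth.

What the generator does **not** emulate: linkage disequilibrium,
ascertainment of the SNP panel, selection beyond the linear climate
effect, observer error and wear/pathology in scoring, non-MCAR
missingness, and real-data idiosyncrasies of population matching. Passing
recovery tests therefore demonstrates estimator correctness and the
qualitative behaviour of the schemes, not performance guarantees on any
real data set.

## Numerical choices

* Pooled scatter singularity is an error advising variable reduction;
  there is no silent ridge/shrinkage, because it would change D² without
  notice. (Near-singularity from the geometric-mean constraint — size
  correction makes log-rows sum to zero — is tolerated down to a relative
  eigenvalue of 1e-12.)
* F_ST undefined estimates (zero denominator) are NaN-flagged and
  excluded from per-pair averages; a pair with no defined locus is an
  error at the full-data stage and a logged redraw inside the loci
  undersampling scheme.
* Genepop allele mapping: the first allele code encountered per locus is
  the reference; downstream F_ST is invariant to the choice (tested).
  Both 2- and 3-digit dialects are supported; any zero allele means
  missing.
* Distance matrices are validated symmetric (1e-9), zero-diagonal and
  finite at construction; F_ST matrices may carry negative entries only
  when flagged.
* The probit sign convention (Φ⁻¹(p) vs Φ⁻¹(1−p)) does not affect D²
  (tested to 1e-10); Φ⁻¹(p) is used.
* Degenerate resampling schemes (nothing to resample) compute the point
  estimate once and replicate it, which is bit-identical to looping.
* All randomness flows through numpy SeedSequence spawn keys; identical
  (inputs, scheme, master seed) runs are bit-identical, and the pipeline
  manifest records artifact checksums to make this checkable.

## Problem sizes used in the packaged runs

The analysis drivers and the acceptance script run the full 26-population
/ 2,000-locus design with 200 resampling iterations per scheme; recovery
corner cases use 100 iterations; the across-seed experiments use 20
master seeds with 25 iterations each; the end-to-end determinism fixture
uses 12 populations, 600 loci and 60 iterations. These sizes are the
package's own choices to keep a complete run in the minutes range on a
single CPU while leaving every qualitative conclusion unchanged; the
iteration count is configurable up to the study-scale 1,000.

## Known limitations and open edges

* The exact-ordering parameter-recovery check (estimated block ordering
  vs per-seed true-signal ordering across 20 seeds) plateaus well below
  certainty: with 26 populations and a handful of effective genetic
  factors per block, adjacent blocks' realized signals frequently differ
  by less than the estimator's residual noise. This is the same
  stochastic-evolution variance the loci-undersampling scheme is designed
  to expose, and the corresponding acceptance test documents the measured
  agreement rather than passing.
* P_ST is a documented standard formulation (σ²_B/(σ²_B + 2h²σ̄²_W) with
  N_e-weighted between-pair variance, averaged over traits) and is marked
  provisional: model-bound comparisons additionally require externally
  validated N_e and h² estimates, so it is off by default.
* NMDS stress values are reproducible only up to local minima; the
  best-of-restarts policy with a classical-scaling warm start makes runs
  stable at the matrix sizes used here, and a cross-implementation check
  agrees within 0.01.
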