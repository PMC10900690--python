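# Methods

## Statistical model

Epistasis between loci is modeled as the interaction coefficient of a linear
regression of a quantitative phenotype on additive genotype codes plus an
encoded interaction term.  With every variable mean-centered (which absorbs
the intercept), the pairwise model is p̃ = β₁g̃ᵢ + β₂g̃ⱼ + β₃Ĩ and β₃ is the
partial association of phenotype and interaction given both main effects.
The implementation computes β₃ and its t-test from partial residuals rather
than a matrix solve:

* resid_I — the interaction residualized on g̃ᵢ and the g̃ᵢ-residualized g̃ⱼ
  (two projection steps; the explicit Schur-complement form of the
  two-predictor normal equations);
* β̂₃ = ⟨p̃, resid_I⟩ / ⟨Ĩ, resid_I⟩;
* T(β₃) = √(n−v−1) · ⟨p̃, resid_I⟩ / √(⟨Ĩ, resid_I⟩·⟨p̃, resid⟩) with v = 3,
  so df = n − 4, and the global-residual inner product obtained from the
  Frisch–Waugh identity ⟨p̃, resid⟩ = ⟨p̃, resid_p⟩ − β̂₃⟨p̃, resid_I⟩.
  The last factor equals ⟨resid_p, Ĩ⟩ because both partial residuals are
  orthogonal to the span of the loci; writing it with the raw centered
  interaction (⟨p̃, Ĩ⟩) instead would *not* be an identity, and the test
  suite asserts the implemented form against explicitly computed OLS
  residuals.

Equivalent routes — the partial correlation r between the standardized
phenotype and interaction residuals, Yule's relation β̂₃ = r·‖resid_p‖/‖resid_I‖,
and the Fisher approximate statistic √(n−v−1)·r/√(1−r²) — are exposed as
diagnostics.  Two-sided p-values use the Student-t survival function.

The dual-route property — that these closed forms agree with a standard
OLS fit with intercept on the raw variables to ~1e−12 relative — is asserted
over a thousand random fixtures in the tests and the acceptance script, and
is the package's core correctness claim.

## Interaction encodings

An encoding is a total map from genotype k-tuples in {0,1,2}ᵏ to reals.
Built-ins: `cartesian` (product) and `xor` (parity of the heterozygote
count; for k = 2 this is the classic exclusive-or penetrance model, value 1
exactly when one locus is heterozygous).  Custom pairwise (9-row) or k-ary
(3ᵏ-row) penetrance tables load from TSV and are validated for totality.
Encodings are applied to raw genotypes *before* centering; pipelines always
encode-then-center, never the reverse.  For k-way models, size-s subsets use
the arity-s form of the chosen encoding; the generalized XOR (parity over s
loci) is this package's natural extension of the two-locus form.

## k-way model

The order-k design has 2ᵏ−1 predictors: k main effects plus one interaction
per subset of size ≥ 2, ordered by size then lexicographically, with the
full-set interaction second-to-last and the phenotype last in an m × 2ᵏ
working matrix Q.  A single in-place sweep removes each column's projection
from all later columns (unnormalized Gram–Schmidt); the projection
coefficient of the phenotype on the residualized full-set column *is* the
OLS coefficient β of the order-k interaction, and the swept phenotype column
is the global residual, giving the T statistic with df = m − (2ᵏ−1) − 1.
Beyond Q only scalars are stored.  The ordering of the preceding columns is
irrelevant to β (the spanned subspace is identical), which a property test
asserts by permuting loci.  k is capped at 6 by default (2ᵏ predictors and
the df guard make larger models pointless at desk sample sizes); the cap is
an argument.  No main-effect pre-screening is offered for scans: a zero
main-effect coefficient carries no implication about the interaction
coefficient, so screening on main effects is not statistically justified;
three-way scans run exhaustively over a user-chosen candidate set.

## Permutation test

For a pair, the interaction residual does not involve the phenotype and is
computed once.  Each of K permutations of the centered phenotype then needs
only ⟨q, resid_I⟩, the two locus projections of q (for ⟨q, resid_p⟩) and the
identity above, evaluated as matrix products against an m × K permuted-
phenotype matrix.  Columns are drawn uniformly and independently (the
identity permutation is not excluded; duplicate columns are possible),
reproducibly from a seed, and may be processed in chunks with bit-identical
results.  The p-value is the fraction of permutations with |T| at least
|T_observed| (default estimator count/K, matching the usual "percentage of
permutations" definition; the (count+1)/(K+1) small-sample correction is a
flag).  Default K = 1000.  Degenerate permutation columns (floating-point
perfect fits) are dropped from the effective K and logged.

## Scan pipeline

* **FDR**: Benjamini–Hochberg over all pairs of one scan (one family per
  scan/encoding), α = 0.05 default, via statsmodels; degenerate (NA) pairs
  are excluded from the family.
* **Structure correction**: all model variables — phenotype, genotypes and
  the raw-genotype-encoded interactions — are premultiplied by a
  user-supplied m × m inverse square root of the phenotypic covariance
  before centering, converting generalized least squares into the ordinary
  problem the closed forms solve.  With the identity matrix the pipeline is
  bit-identical to the uncorrected one; a scalar matrix leaves β and T
  unchanged.  Computing the covariance (GRM + variance components) is out of
  scope; the pipeline consumes the matrix.
* **MLG filter**: each pair's nine two-locus genotype counts (complete cases)
  must all reach a threshold (0 = off; 10 and 5 are the conventional rat- and
  mouse-scale choices).  The flag is carried in the table and does not alter
  the test family.
* **Redundancy pruning** (10-Mb window, strict <, in order): (1)
  interchromosomal redundancy — slot-wise chromosome match and both slot
  distances inside the window; the pair with the lower FDR-adjusted p is
  retained; (2) mirror redundancy — the same with slots swapped; the pair
  encountered first in table order is retained (row order is fixed as locus-
  index order i < j, making the rule deterministic); (3) intrachromosomal
  redundancy — same distance criteria, lower q retained; (4) cis removal —
  intrachromosomal pairs whose own loci are closer than the window are
  dropped.  Pruned rows stay in the table with a `pruned_reason`.
* **QTL annotation**: a locus within the window of a QTL takes the QTL's
  label; when several QTLs qualify the nearest wins (ties resolve to the
  lexicographically smallest id).  Non-QTL loci on a chromosome are chained
  in ascending bp order — a locus joins the current cluster while within the
  window of its predecessor — and every member is replaced by the chain's
  average position.  Chaining is single-pass and greedy; a chain can span
  more than one window end-to-end, which is accepted and covered by tests.
  Pairs are classified QTL-QTL / QTL-nonQTL / nonQTL-nonQTL; per-locus
  interaction counts sum to twice the pair count.
* **Hubs**: loci with ≥ 10 interactions (threshold exposed), sorted by count
  then label.
* **LD diagnostics**: D′ and r² per pair from unphased genotypes via EM
  under HWE — only the double heterozygote is phase-ambiguous and its mass
  is reallocated each E-step (convergence 1e−8, cap 1000 iterations).
  Hand-written because no installed dependency offers composite-haplotype EM;
  the tests check it against an independent direct maximization of the
  HWE multinomial likelihood.

## Synthetic data

The generator emulates the statistical shape of the model-specificity
simulation design: independent biallelic HWE loci (genotype ∼ Binomial(2,
MAF)), a Gaussian base phenotype, and pairwise interactions embedded by rank
reassignment.  Defaults are the study conditions used throughout the tests:
m = 2000 samples, 18 loci, nine adjacent embedded pairs, per-pair
reassignment fraction 0.3, residual noise sd 0.5 (phenotype base sd 1), and
MAF 0.5.

Two generator choices were genuinely open and deserve their rationale:

* **Joint embedding.**  Each embedded pair contributes its standardized
  interaction over its own random 30% of samples to a composite score; the
  touched samples' phenotype values are then redistributed once, in rank
  order of the composite (random tie-break), preserving the phenotype
  multiset.  The alternative — reassigning each pair's subset sequentially —
  destroys earlier pairs' alignment whenever subsets overlap (about 0.7⁸ of
  the first pair's signal would survive nine passes), and cannot make all
  nine pairs detectable at once.  The joint scheme gives every embedded pair
  an expected |T| ≈ 7 at m = 2000, consistent in magnitude with what the
  design is meant to produce.
* **Balanced allele frequencies.**  Under the map g → 2−g the heterozygote
  indicator is invariant while the genotype and product terms reflect, so at
  MAF 0.5 the XOR term is exactly orthogonal to {g̃₁, g̃₂, g₁g₂} and
  XOR-embedded signal is structurally invisible to a Cartesian-term scan.
  Away from 0.5 that orthogonality fails and part of an XOR signal leaks
  into the product term — the model-exclusivity property the generator
  exists to exhibit is an allele-frequency-dependent fact, not an automatic
  one.  The default therefore uses MAF 0.5; `mafs` accepts any per-locus
  values in (0, 0.5] for studying the leakage itself.

Loci are placed on five synthetic chromosomes 25 Mb apart (outside the
default pruning window) so annotation-dependent code can be exercised; an
optional copy-with-flip mode creates LD between adjacent loci solely to
exercise the pruning and LD code.  Not emulated: realistic allele-frequency
spectra, linkage disequilibrium structure, relatedness/population structure,
and missingness — so passing tests demonstrate algorithmic correctness and
the encoding-specificity property under idealized sampling, not performance
on structured cohort data.

## Numerical choices

* A squared norm counts as zero below 1e−12 × m × (variance scale); such
  degeneracies (monomorphic or collinear loci, interaction collinear with
  loci, perfect fits) raise a typed error in single-fit mode and become
  logged NA rows in scan mode.
* All accumulation is double precision; no compensated summation (adequate
  for m ≤ 1e6).
* Pairwise df is fixed at n − 4 (two loci + interaction + absorbed
  intercept); sample count appears as m or n interchangeably.
* Missing genotypes/phenotypes are complete-cased per pair (per locus set
  for k-way).  Structure-corrected scans require complete data, since the
  whitening transform does not commute with case deletion.
* BH q-values and rejections come from statsmodels' `multipletests`;
  p-values outside [0, 1] are rejected.
* The permutation estimator reports count/K by default; chunk size only
  affects memory.

## Problem sizes in tests and the acceptance script

Unit and property tests run at m between 10 and a few hundred; the oracle-
equivalence sweep uses 1000+ random fixtures with m ∈ [10, 200]; the
model-specificity scan runs the full study conditions (m = 2000, 153 pairs,
both encodings); permutation calibration uses K = 1000 at m = 400; the null
calibration aggregates ~2,300 independent pairs.  These sizes were chosen so
the whole suite completes in seconds while leaving every statistical check
well-powered.

## Known limitations

* The k-way sweep is O(2²ᵏ m) per locus set; exhaustive k-way scans over
  many loci are out of scope by design (candidate sets only).
* The LD EM assumes HWE and random union of gametes; strong inbreeding
  violates it.
* Covariate adjustment is expected to happen upstream (regress covariates
  out of the phenotype first); the model itself carries no covariates.
* The pruning rules are order-dependent by specification (mirror redundancy
  keeps the first-encountered pair); determinism is guaranteed by the fixed
  row order, not by symmetry.
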