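# Methods

## Model

The pipeline connects three tables: a compounds × isotypes binding-energy
matrix *E* (kcal/mol, docking sign convention — more negative is stronger
binding, never flipped), per-cell-line isotype abundance fractions *w* on
the probability simplex, and a compound × cell-line IC₅₀ panel (µM) with
right-censoring. The weighted binding energy of compound *c* in a cell
line is the convex combination BE_w(c) = Σᵢ wᵢ E(c, i); the statistical
model behind the correlation stage is

    log₁₀ IC₅₀(c, line) = β₀ + β₁ · BE_w(c, line) + ε,   ε ~ N(0, σ²)

fit per cell line by ordinary least squares. R² is the coefficient of
determination (equal to the squared Pearson correlation in the univariate
case), and is invariant to affine transformations of either variable, so
the choice of log base and of concentration unit (µM vs M) cannot change
any reported R². Descriptor rows of the panel (TPSA, MlogP, HBD, POL) use
the same response with a cell-line-independent predictor; the bivariate
model adds TPSA next to BE_w, and by nesting its R² can never fall below
the univariate BE_w value on the same rows.

## Abundance profiles

Three constructors, for three data situations:

* `normalize_expression` — raw nonnegative expression values are divided
  by their sum (scale-invariant; counts, TPM or percentages all give the
  same profile).
* `average_profiles` — for a cell line without its own profile, the
  unweighted mean of related profiles (e.g. a tissue average). Averaging
  is done on normalized fractions, not raw values, so each contributing
  line counts equally regardless of sequencing depth; the mean is
  renormalized to sum exactly to 1.
* `uniform_profile` — equal weight 1/k over an explicitly listed isotype
  set, the weakest assumption when no expression data exist. The caller
  must name the isotypes; the package does not guess which are "usually
  most expressed".

Gene-keyed expression files are translated through an editable
`TUBB→βI, TUBB2A→βIIa, TUBB2B→βIIb, TUBB3→βIII, TUBB4→βIVa, TUBB2C→βIVb`
map; files whose row labels match no mapped gene are taken as
isotype-keyed verbatim, since energy tables label isotypes (αβI, αβIIa,
…) with names that are not gene symbols. Label mismatch between a profile
and a matrix is an error by default; `restrict_to_matrix` (CLI
`--restrict-to-matrix`) explicitly drops extra isotypes and renormalizes.

## Censoring

The only censor grammar is `>X` (right-censored at X µM), matching how
IC₅₀ panels report compounds that never reach 50% inhibition in the
tested range. "mean ± SD" cells keep the mean; the SD is stored but
unused, since the correlation stage works on point values. The default
policy `exclude` drops censored entries from fits rather than fabricating
a value; `at_bound` imputes log₁₀(bound) and biases fits toward the
censoring floor — every report states which policy and log base produced
it, with per-cell-line exclusion lists. Tobit-style censored likelihoods
are deliberately out of scope: the pipeline mirrors a plain linear-model
analysis.

## Consistency diagnostics

A weighted energy is a convex combination of its row, so
row-min ≤ BE_w ≤ row-max is a necessary condition for *any* abundance
profile; `hull_check` reports the violation distance per compound.
`recover_weights` solves the inverse problem

    min ‖E·w − bw‖²  s.t.  w ≥ 0, Σw = 1

a convex QP, via SLSQP started deterministically at the uniform vector
(gradient supplied; ftol 1e-14). The fitted values E·w* are unique even
when the weights are not; a rank-deficient matrix is flagged
`non_unique` and the reported weights are then refined to the
minimum-norm minimizer by a second QP constrained to the optimal fitted
values. Feasibility tolerance: 0.02 kcal/mol by default, i.e. 4× the
0.005 rounding half-width of tables printed to 2 decimals — calibrated by
the synthetic rounding experiment below, which shows 2-decimal rounding
alone produces worst-case residuals well under this bound, so residuals
above it indicate genuine inconsistency, not rounding noise. Inconsistent
published pairs are surfaced as warnings in the `diagnose` report, never
as crashes: on the bundled pair, 36 of 63 entries are out of hull
(compound 4 above its row maximum and compound 20 below its row minimum
in every cell line) with best-fit residuals ≈ 0.5 kcal/mol, and the
recomputed BE_w R² row (0.04–0.39) does not match the published one
(0.51–0.64). Both findings are reported as data-provenance observations;
the package asserts its own computations, not the published values.

## Synthetic data

The generator emulates the study conditions at their real scale — 9
compounds, 9 isotypes, 7 cell lines:

| parameter | default | rationale |
|---|---|---|
| mean energy | −8.5 kcal/mol | center of the observed docking range (−7.1 to −9.7) |
| compound effect SD | 0.5 kcal/mol | between-compound spread dominates |
| isotype effect SD | 0.15 kcal/mol | isotype selectivity is weak |
| residual SD | 0.1 kcal/mol | compound × isotype interaction |
| Dirichlet concentration | 1.0 (flat) | realistically uneven abundance profiles |
| slope β₁ | 1.2 per kcal/mol | stronger binding → lower IC₅₀ on the observed scale |
| intercept β₀ | 11.8 | places IC₅₀ in the tens of µM (β₀ + β₁·(−8.5) ≈ 1.6 log units) |
| noise SD | 0.1 log units | visible but non-dominant scatter |
| censor bound | 100 µM | assay ceiling |

Energies are additive Gaussian (mean + compound + isotype + residual),
profiles are symmetric-Dirichlet draws, and potencies follow the linear
logIC₅₀ model exactly — which is what makes the generator a ground-truth
oracle and also what it does *not* share with real data: no isotype ×
compound selectivity structure beyond the residual term, no non-linearity
or heteroscedasticity in potency, no correlated abundance profiles across
related cell lines, and no assay-level variation (the printed SDs). A
passing recovery test therefore demonstrates the pipeline's correctness
under its own assumptions, not that real docking scores predict real
potencies. One root seed expands into per-stage child seeds
(root·1000 + {1, 2, 3} mod 2³¹−1 for matrix/profiles/potency), so stages
are independently reproducible and regeneration is bitwise stable.

Validation experiments (seeded; rerun by `analysis/04_synthetic_validation.py`
and `scripts/acceptance.py`): per-cell-line OLS recovers the true slope
within ±3 SE at noise 0.1; `recover_weights` reproduces noiseless weighted
columns to residual RMS ≤ 1e-6 and stays ≤ 0.02 kcal/mol after 2-decimal
rounding of both tables; with slope 0 the mean R² over 10,000 replicates
matches the Gaussian-null expectation 1/(n−1) = 0.125 (R² ~ Beta(½, (n−2)/2)
under the null) within Monte-Carlo error.

## Numerical and design choices

* Delimiter auto-detection is limited to tab and comma; the decimal
  separator is always a period (comma decimals are a parse error naming
  the cell). Unicode minus and ASCII hyphen are interchangeable on input.
* Writers emit the shortest decimal representation that round-trips the
  float exactly, so write-then-read is identity for all table types.
* Compound ids are opaque strings ("4", "CA4", "colchicine").
* A reported fit needs n ≥ 3 (n ≥ 4 bivariate); constant or collinear
  predictors raise a degenerate-fit error; cells with insufficient
  overlap are reported as missing with a reason, never silently 0.
* No multiple-testing correction across the 5 × 7 panel: the R² values
  are descriptive, matching the analysis style the pipeline reproduces.
* Descriptor values are ingested as columns; the optional RDKit helper
  computes TPSA/HBD exactly, Crippen logP for the MLogP column and molar
  refractivity for POL (proportional to polarizability), recording the
  engine and version in the frame's metadata. Bundled descriptor values
  for the nine docked compounds are not shipped because their structures
  are not machine-readable from the source tables.

## Known limitations

* The bundled weighted table cannot be regenerated from the bundled
  energy matrix (see diagnostics above), so end-to-end reproduction of
  the published correlation panel from first inputs is impossible; the
  pipeline documents this instead of papering over it.
* `exclude` censoring discards information; with heavy censoring the
  per-cell-line n drops and R² becomes unstable (the reports expose
  n_used for exactly this reason).
* The inverse weight recovery assumes a single static abundance profile
  per cell line; it cannot represent mixtures that change with treatment.
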