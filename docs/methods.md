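# Methods

This note records the scientific conventions, defaults and design choices the
package commits to, and what its synthetic benchmarks do and do not show.

## Molecular graphs and atomic properties

Molecules are hydrogen-depleted labelled graphs.  SMILES parsing, aromaticity
perception and valence checking are delegated to RDKit; aromatic bonds carry
order 1.5.  Topological distance is the shortest-path bond count (every bond
one edge, regardless of order) computed by breadth-first search.

Atomic property weights (mass, van der Waals volume, Sanderson
electronegativity, polarizability) live in a packaged CSV whose header cites
the sources (IUPAC atomic weights; Bondi radii volumes; Sanderson scale; CRC
polarizabilities).  By default every weight is **carbon-scaled** (divided by
the carbon value), the convention the Dragon descriptor software documents;
raw weights are available by constructing the table with
`carbon_scaled=False`.  Elements covered: H, C, N, O, F, Si, P, S, Cl, Br, I.

## Descriptor kernels

With w the weight vector, w̄ its mean, A the atom count and the sums running
over **ordered** atom pairs (i, j) at topological distance d (Δ of them):

* Moran  I(d) = [Δ⁻¹ Σ (wᵢ−w̄)(wⱼ−w̄)] / [A⁻¹ Σᵢ (wᵢ−w̄)²]
* Geary  c(d) = [(2Δ)⁻¹ Σ (wᵢ−wⱼ)²] / [(A−1)⁻¹ Σᵢ (wᵢ−w̄)²]
* Broto-Moreau  ATS(d) = Σ_{i<j} wᵢwⱼ  (unordered pairs)

These are the standard spatial-statistics forms (population variance for
Moran, sample variance for Geary).  Degenerate cases return 0, never NaN:
zero weight variance, or no atom pair at the lag (lag beyond the diameter).
This keeps matrix assembly total; the prefilter later removes the resulting
constant columns.

Burden matrix: diagonal Bᵢᵢ = wᵢ; bonded pairs Bᵢⱼ = 0.1 × bond order with
aromatic = 1.5; all non-bonded pairs 0.001.  BEHwk is the k-th largest
eigenvalue, BELwk the k-th smallest.  The constants (0.1, 0.001, 1.5) are
frozen here.

Descriptor names follow the Dragon grammar (family + lag/rank + weight
letter; `u` = unweighted).  One naming wrinkle inherited from the source
tables: the descriptor printed as "GATS8P" is glossed there as a *Moran*
autocorrelation; the G prefix makes it a Geary coefficient and it is
implemented as such.

Prefiltering removes columns with sample SD ≤ 1e-8 (raw scale), then scans
column pairs in fixed name order and drops the **later** column of any pair
with |Pearson r| above the cutoff (default 0.95).  The tie-break is a
convention chosen for determinism and logged per removal; prefiltering is
idempotent.

## Dataset handling

pIC₅₀ = −log₁₀(IC₅₀ in mol/L), exact, with rounding only at display time.
Several printed literature values disagree with this arithmetic by one or a
few units in the second decimal; the packaged fixtures keep the printed
values and flag each row's self-consistency (see the fixture NOTES).

Kennard–Stone runs on Euclidean distances over autoscaled descriptors (the
algorithm's standard form; the source does not state the metric).  Seed pair:
the two mutually farthest points; then repeatedly the candidate maximizing
the minimum distance to the selected set; all ties broken by lowest row
index, so the split is deterministic.  Autoscaling uses the sample SD
(n−1 denominator) everywhere; new rows are always scaled with the stored
training statistics.  The PCA homogeneity check is ordinary PCA (scikit-learn)
on the autoscaled matrix.

## Regression

MLR is least squares with intercept, reporting coefficient SEs, R² and the
F-ratio.  Stepwise selection is forward entry (smallest partial-F p-value
< α_enter, default 0.05) with backward elimination (p > α_remove, default
0.10); thresholds are conventional defaults, configurable, since the source
does not state them.

PLS is a hand-written single-response NIPALS with internal autoscaling of X
and y.  NIPALS was chosen over a library call because its nested deflation
yields the whole coefficient path (1..a latent variables) from one pass,
which makes the RMSECV curve and the GA fitness cheap; sklearn's
PLSRegression serves as an independent cross-check in the test suite.  At
full rank PLS reproduces OLS to 1e-8, which is the oracle the tests enforce.
Latent-variable count is the argmin of RMSECV with ties resolved toward fewer
components (parsimony).

Residual convention throughout: **residual = predicted − experimental**,
matching the published test-set tables.

## GA-PLS

Chromosomes are binary inclusion vectors; fitness is
100·[1 − (n−1)/n · SSE_cv/SS_y] computed from random-subset CV predictions
(4 subsets, re-randomized each generation from the run's RNG stream).  The
inner LV count is chosen per chromosome by CV, capped at min(10, bits set).
Selection is fitness-proportional with a rank fallback when the spread is
degenerate; crossover is two-point ("double"); mutation is per-bit at rate
0.003; a single elite individual is preserved, which makes the elite fitness
trajectory non-decreasing by construction.  The run stops at 100 generations
or when 80% of the population shares the elite fitness.  `window_width` is
carried in the configuration for completeness but is inert: the source
parameter table lists it without definition, and no interpretation
recoverable from the text changes the per-bit mutation operator.  All
randomness flows from one seed; runs are bit-for-bit reproducible.

## Validation battery

REP% = 100·RMSE/ȳ; RMSE with the 1/n convention; external
Q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)² centred on the **training** mean.  The
literature often labels this quantity LOO-Q²; both are standard and the
package exposes them separately (`q2_loo` centres on the evaluated set's own
mean).  Tropsha battery: k = Σyŷ/Σŷ², k′ = Σyŷ/Σy²; R₀² is computed with the
predicted-value deviations in the denominator (the form printed in the
source), with the experimental-deviation variant available behind a flag.
Y-randomization re-runs a caller-supplied builder on uniformly shuffled
activities; the builder defines which (R², Q²) pair is reported, because the
published shuffled statistics are only reachable as external/CV quantities —
a supervised PLS component fitted to shuffled y inflates *training* R² by
roughly p/n even under the null.  Mean effects MF_j = β_j Σᵢ d_ij / Σⱼ β_j
Σᵢ d_ij are computed on raw descriptor values and sum to 1 by construction.

## Applicability domain

Leverage h = xᵀ(XᵀX)⁻¹x.  The source prints this formula without the matrix
inverse; the standard definition is implemented, since the printed form is
not scale-invariant and would contradict the meaning of the h* = 3(p+1)/n
threshold it is compared against.  For PLS models the model space is the
latent-variable score space with p = number of LVs (consistent with
3(8+1)/108 = 0.25 for an 8-LV model trained on 108 compounds); for MLR it is
the autoscaled selected-descriptor space.  A pseudo-inverse with a warning is
used when XᵀX is ill-conditioned.  Standardized residual = residual / sample
SD of training residuals, cut off at ±3; probes without measured activity are
classified on leverage alone (as screening requires).

## Screening

Scaffolds carry numbered atom-mapped dummy atoms (`[*:1]`); substituents are
fragments with the matching dummy, grafted with RDKit `molzip`.  Invalid
grafts are rejected and logged.  Candidates are predicted with the fitted
model, classified against the training AD, and ranked among the in-domain
set only; out-of-domain candidates are retained with their flag, never
dropped.  A sequential two-round screen (optimize ring substituents, then
modify the best candidate's core) is expressed as two spec files, not special
logic.

## Synthetic benchmark conditions

`gen_descriptor_data` defaults — n = 120 compounds, p = 50 descriptors, 5
informative with β = 2, noise SD 0.3, correlation 0.5 induced by
latent-factor mixing — define the planted-recovery benchmark used by the
tests and the acceptance script.  The sizes mirror the scale of the study the
pipeline targets (≈130 compounds, a few hundred filtered descriptors reduced
here for desk-scale runs); the factor-mixing collinearity emulates the
redundancy among real 2D descriptors that motivates PLS and GA selection.
`gen_molecules` draws random valence-respecting trees with optional ring
closures over {C, N, O, S, F, Cl, Br}, biased toward carbon.

What passing these benchmarks shows: the pipeline's machinery (kernels,
splitting, regression, selection, validation, AD) is numerically correct and
recovers planted sparse linear structure under realistic collinearity and
noise.  What it does not show: performance on real medicinal-chemistry
series, where descriptor–activity relationships are not exactly linear,
noise is not Gaussian, and chemical series induce clustered (not factor-
mixed) correlation structure.

## Numerical choices and limitations

* Sample SD (ddof = 1) everywhere; near-constant tolerance 1e-8 on raw SD.
* NIPALS terminates a component when the weight or score norm falls below
  1e-12; coefficient paths are flat beyond the effective rank.
* The Williams analysis refuses to standardize residuals when the training
  residual SD is numerically zero (relative threshold 1e-12).
* Problem sizes in the test and acceptance runs (1 000 oracle graphs ≤ 12
  atoms, 5 GA seeds at the default benchmark, 10 Y-randomization shuffles)
  are the package's chosen desk-scale defaults.
* Known source inconsistencies are documented rather than modelled: a
  training-equation sample size printed as n = 122 against a 108-compound
  training set; a coefficient column in the published model table that is
  permuted relative to the regression equation printed beside it (neither is
  used as a numeric target); the activity-table discrepancies listed in the
  fixture NOTES.
* Out of scope by design: 3D descriptor families (RDF, 3D-MoRSE, WHIM,
  GETAWAY, geometrical, charge) and semi-empirical geometry optimization —
  precomputed descriptor CSVs can be imported instead; multi-response PLS;
  regularized regressions; alternative AD definitions.
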