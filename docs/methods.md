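# Methods

`radsurv` implements a prognostic-modelling pipeline for tumor MRI: raw
radiomic feature extraction from a 3D volume plus segmentation, feature
consolidation and redundancy filtering, latent-factor compression by
regularized maximum-likelihood factor analysis, and Cox survival modelling
evaluated by integrated time-dependent AUC. This note records the models,
the conventions behind every numerical choice, and what the synthetic data
do and do not establish.

## Image model and feature bank

Volumes are 3D scalar arrays in (x, y, z) index order with physical voxel
spacing (dx, dy, dz) in mm; the "x-y plane" is an axial slice. Masks are
binary on the same grid (any nonzero voxel is foreground); grid agreement is
enforced to 1e-3 mm. Features are computed on the native, possibly
anisotropic grid by default; optional isotropic resampling (tri-linear for
images, nearest-neighbour for masks) is off by default because the feature
bank deliberately computes both per-slice 2D and volumetric 3D texture,
which presupposes the native slice structure.

The raw bank has exactly 545 features in seven families:

| family | count | gray-level handling |
|---|---|---|
| first-order statistics | 35 | 9 whole-image + 20 raw-VOI + entropy/uniformity at 32/64/128 bins |
| spatial autocorrelation (Moran's I, Geary's C) | 2 | raw intensities |
| intensity-volume histogram AUC | 1 | min-max scaled intensities |
| morphology | 11 | mask only |
| fractal | 4 | mask only |
| gray-level co-occurrence (GLCM) | 300 | 25 features x {32,64,128} bins x {averaged, merged} x {2D, 3D} |
| gray-level run length (GLRLM) | 192 | 16 features x the same 12-cell grid |

Discretization is fixed-bin-number over the VOI's own min-max range:
`g = min(n_bins, 1 + floor(n_bins (x - min)/(max - min)))`, constant VOIs
mapping to level 1. This makes every discretized feature invariant to
strictly increasing affine intensity maps — the mechanism by which gray-level
normalization barely moves the texture features (see Concordance below).

Conventions that the main text of a feature taxonomy typically leaves open
are fixed as follows and unit-tested:

- Quantiles (median, IQR) use the linear-interpolation rule; skewness and
  kurtosis are population moments, reported as 0 on constant data (excess
  kurtosis likewise); kurtosis is reported both raw and as excess.
- "Values over 0.5" statistics min-max scale the whole image to [0, 1] and
  keep strictly-greater-than-0.5 voxels (a cheap background/air exclusion);
  on a constant image the selection is empty and the sentinel applies.
- Max_star averages the largest VOI voxel (first in lexicographic order on
  ties) with its six face neighbours, reading neighbours from the image and
  ignoring out-of-grid positions.
- The mean Laplacian is the 6-neighbour discrete Laplacian averaged over the
  VOI with zero-flux boundary at the mask edge (an out-of-mask neighbour
  contributes the centre value).
- Undefined statistics (coefficient of variation at mean 0, Moran/Geary on a
  constant VOI) either raise or are replaced by a configurable sentinel
  (default 0) so `extract_all` always emits a complete finite vector; the
  policy is part of `ExtractionConfig`.
- Total energy and integrated intensity are volume-weighted
  (`sum x^2 * voxel_volume` and `mean * VOI volume`).
- Spatial autocorrelation uses binary rook (6-neighbour) weights restricted
  to in-mask pairs.
- The IVH curve nu(t) (fraction of voxels with scaled intensity >= t) is
  integrated by trapezoid on a 1000-point grid; a constant VOI is
  all-maximum by convention (AUC 1).

Texture engines use neighbour distance 1 voxel in index space (anisotropy
ignored — the universal radiomics default), symmetric GLCMs, 13 unique 3D
directions and 4 in-plane 2D directions with per-slice matrices summed over
all slices. "Averaged" computes features per direction and averages;
"merged" sums direction matrices and computes features once. The merged
run-percentage denominator counts each voxel once per direction. Degenerate
single-level matrices take correlation 1 and information-correlation
measures 0. Both engines are verified cell-by-cell and feature-by-feature
against brute-force double-loop oracles on random small VOIs (relative
tolerance 1e-9).

Morphology: volume is voxel count x voxel volume; surface area comes from
marching cubes at iso-level 0.5 after anti-aliasing the padded binary mask
with a 0.8-voxel Gaussian — on a digital radius-20 ball this brings the
triangulated area within ~0.3% of the analytic sphere, where the raw binary
mesh overestimates by ~8%; masks thin enough that smoothing erases the
level crossing fall back to the raw mesh. The maximum 3D diameter is the
largest pairwise vertex distance, computed on the mesh convex hull. The
derived descriptors (compactness 1/2, sphericity, spherical disproportion,
asphericity, equivolumetric-sphere quantities) are pure functions of (V, A),
kept in a separate formula layer so they can be validated on analytic solids
independently of meshing error. The surface-to-equivolumetric-sphere ratio
and spherical disproportion are the same functional; both are emitted
because the bank enumerates them as distinct named features.

Fractal features use dyadic box counting anchored at the bounding-box
corner, scales 1, 2, 4, ... up to half the largest bounding-box edge. The
"fitted" dimension is minus the OLS slope of log N(s) on log s, the
"calculated" dimension the mean of adjacent-pair slopes, abundance the
exponentiated fitted intercept (fitted N at s = 1), and lacunarity the
gliding-box statistic 1 + var(M)/mean(M)^2 at s = 2 over boxes fully inside
the bounding box. The fitted/calculated distinction is this package's
documented choice; both reduce to the exact dimension on exactly self-similar
inputs (filled cube: 3; voxel line: 1).

## Normalization and concordance

Five gray-level normalizations are registered: min-max, z-score,
median/IQR, percentile clip (1st–99th) + rescale, and rank-based histogram
equalization — spanning linear, robust-linear and rank-based families. The
registry is pluggable. Robustness of features to normalization is
quantified per feature by Kendall's coefficient of concordance W across
extraction conditions (conditions as raters ranking patients), with the
tie-corrected formula. Because discretized texture features are invariant
to monotone-affine maps, they achieve W = 1 under the affine methods
exactly; W < 1 arises only for features reading raw intensity scale. High
concordance is the quantitative justification for modelling unnormalized
data.

## Consolidation, stability, redundancy

Variants of one quantity (bin counts x aggregation x dimensionality for
texture; bin counts for first-order entropy/uniformity) are averaged into a
single core feature keyed by (family, name), giving 90 core features from
the 545 raw ones. The grouping map is explicit and configurable.
Interobserver stability scores each core feature by Kendall's W between two
observers' segmentation-derived values, against a 0.7 bar for "high
concordance".

Redundancy filtering iterates: while any feature pair has |Pearson r| above
tau (default 0.95), drop the member of the worst pair with the larger mean
absolute correlation to the remaining features; exact ties drop the
lexicographically smaller id. The removal log (removed id, partner, trigger
correlation) replays deterministically.

## Factor model

The filtered feature matrix is standardized (training mean/SD) and its
correlation matrix shrunk convexly toward the identity,
`R(lambda) = (1-lambda) R_sample + lambda I`; lambda is chosen by 5-fold
cross-validated Gaussian log-likelihood over a log-spaced grid (or fixed).
Off-diagonal magnitudes are non-increasing in lambda, so shrinkage only ever
tempers the sample correlations.

Maximum-likelihood factor analysis fits `R ≈ ΛΛᵀ + diag(Ψ)` by
concentrating the Wishart discrepancy over Ψ (for fixed Ψ the optimal Λ is
an eigensolution of Ψ^{-1/2} R Ψ^{-1/2}); the concentrated objective in
log Ψ is minimized with L-BFGS-B using its analytic gradient, started from
the Jöreskog principal-axis heuristic with seed-controlled jittered restarts
(max 5) on failure. Uniquenesses are bounded below by a floor (default
0.005): a solution pinned at the floor is a Heywood case, recorded on the
model and optionally escalated to an error. A log-barrier of weight 1e-7 on
the uniquenesses breaks the tie in likelihood-flat directions (a diagonal R
admits a manifold of exact solutions) toward the parsimonious Ψ → 1
solution; it is orders of magnitude below the curvature of any informative
fit. Loadings are varimax-rotated (orthogonal, no Kaiser normalization),
sign-fixed so each factor's largest loading is positive, and ordered by
explained variance (sum of squared loadings / p).

The factor count is selected as the smallest m whose ML solution reaches a
cumulative explained-variance target, default 0.75 — chosen to bracket the
upper-70s percentages typical of radiomic feature sets compressed to about
seven factors; Kaiser (eigenvalues > 1) and sequential likelihood-ratio
rules are available alternatives. One interaction to be aware of: at small n
the cross-validated shrinkage is substantial and dilutes every communality
by roughly (1 - lambda), so the variance rule can select more factors than
the generative count even when the structure is clean; when the factor count
is known or fixed by design, set `n_factors` explicitly (the rule recovers
the generative count reliably once n is in the high hundreds). Per-patient scores are Bartlett weighted
least squares, `F = (ΛᵀΨ⁻¹Λ)⁻¹ΛᵀΨ⁻¹ z`; validation cohorts are standardized
with the frozen training mean/SD — required for honest external validation
in a two-center design. Batch effects of scanner vendor and field strength
are tested by one-way MANOVA on the score columns (Pillai's trace with its
F approximation) plus per-factor univariate ANOVAs; groups must have at
least m + 1 members each.

## Survival models and evaluation

Cox proportional-hazards models (partial likelihood, Efron ties, via
lifelines) are fit for four covariate rosters: radiomic (the m factor
scores), clinical (N-stage as an ordinal linear term, age, gender — ordinal
coding because cohort-sized data cannot support full factor coding of
N-stage), tumor volume alone (log volume, since volume spans orders of
magnitude), and combined (factors + clinical).

Discrimination is the cumulative/dynamic time-dependent AUC(t) with inverse
probability-of-censoring weights, evaluated at every unique event time in a
window (default the 2.5th–97.5th percentile of observed event times,
truncated below the last follow-up time as the IPCW estimate requires) and
integrated with weights proportional to the empirical event density. The
censoring distribution for the weights is estimated on the evaluated cohort.
The resulting iAUC is invariant to strictly increasing transforms of the
risk score, and with a single time point and no censoring it reduces exactly
to the Mann-Whitney statistic between cases and controls (tested to 1e-12).

Confidence intervals are nonparametric patient-level bootstrap percentile
intervals (default B = 1000; analyses here use B = 200 where a CI is only a
summary); a statistic failing on more than 10% of resamples aborts. Risk
stratification splits at the median linear predictor of the evaluated
cohort (ties fall to the high-risk arm) with a two-sample log-rank test.
Model comparison uses a paired bootstrap of the iAUC difference with a
two-sided sign-proportion p-value.

`run_study` trains all rosters on the training cohort and evaluates on both
cohorts. On validation the radiomic model is frozen; clinical (and
volume-only) coefficients are refit on the validation cohort with the
roster fixed; the combined model is recalibrated with the frozen radiomic
linear predictor entering as a single covariate refit jointly with the
clinical covariates — the factor weights inside the radiomic predictor
never move. This is one concrete reading of "recalibration of clinical
coefficients allowed"; refitting everything including the factor weights
would leak validation outcome information into the radiomic signature.

## Synthetic data: what it emulates and what it does not

Phantoms are (optionally lobulated) ellipsoids with analytic volume
4/3·π·abc, filled with constant, iid-noise, checkerboard, or Gaussian
random-field texture (Fourier filtering of white noise with an isotropic
squared-exponential spectrum; correlation length in mm so resampling
semantics stay physical), over a flat background. Tabular cohorts draw
features from `x = Λf + Ψ^{1/2}ε` with standard-normal factors and noise,
simple-structure loadings of strength 0.9 by default (strong, clearly
separated factors), survival times from an exponential baseline with hazard
`h0 exp(βᶠf + βᶜclinical)`, and independent exponential censoring whose
rate is solved (Brent) so the expected censored fraction matches the target
(default 0.45, a typical head-and-neck follow-up range). The two-center
preset pairs cohorts of 102 and 76 patients, p = 50 features, m = 7
factors, prognostic signal on two factors (log hazard ratios 0.7 and 0.5
per score SD) and weak clinical effects.

Everything is a pure function of (spec, seed). What passing tests show:
the estimators recover known generating structure (loadings, factor count,
Cox coefficients), the evaluation statistics are calibrated under the null,
and the qualitative two-center ordering (combined ≥ radiomic > clinical
when factors carry the signal) is reproduced. What they do not show:
performance on real MRI — phantoms have no acquisition physics (bias
fields, Rician noise, partial volume), masks are exact rather than
observer-drawn, and tabular cohorts are exactly factor-structured with
proportional hazards holding by construction.

## Problem sizes in the shipped checks

The default verification suite runs feature extraction on 64-cube phantoms,
oracle comparisons on 100 random VOIs up to 6 cubed, factor recovery on 50
seeds at n = 1000, p = 50, null-iAUC calibration on 200 replicates at
n = 500, bootstrap coverage on 500 replicate experiments at B = 200, and
the two-center study on 50 seeds at n = 102/76 — sizes at which every
stochastic check has comfortable Monte-Carlo margin while the whole suite
completes in a couple of minutes on one CPU.

## Known limitations

- GLCM/GLRLM distance is fixed at one voxel and ignores anisotropy; no
  wavelet- or filter-bank feature classes.
- The five normalization methods are this package's registry, chosen to
  span transform families; a study with a prescribed set can register its
  own.
- The exact 89-versus-90 core-feature count depends on one unresolvable
  grouping detail; the default grouping yields 90 and is configurable.
- Factor labels (e.g. "3D geometrics") are free-text annotations on the
  model object, not derived quantities.
- Oblique rotations, Bayesian factor models, and explicit batch correction
  (e.g. ComBat) are out of scope; MANOVA only flags batch effects.
- The iAUC estimator (IPCW cumulative/dynamic, event-density weights) is one
  member of a family; incident/dynamic variants would need a different
  weighting and are pluggable at the `integrated_auc` seam.
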