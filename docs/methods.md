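# Methods

This note records the statistical model, the conventions the implementation
pins down where the field leaves them open, the synthetic-data design, and
the package's known limitations.

## Data model and filtering

The canonical unit is one (possibly pooled) sample with δ13C and δ15N for
ten amino acids (alanine, valine, glycine, isoleucine, leucine, proline,
aspartic acid, phenylalanine, glutamic acid/Glx, lysine), plus bulk δ13C,
δ15N and δ34S, all in ‰, labelled by species, collection year and site.
Analyses use complete cases only: a row enters the pipeline only if all 20
amino-acid values and bulk δ34S are finite. No imputation is attempted —
partial isotope profiles are rare enough in compound-specific datasets that
imputation would add model risk for little gain. Bulk δ13C/δ15N may be
missing without dropping a row; they are used only for proxy validation.

## Dimension construction

PCA is computed on the correlation matrix (each tracer centered and divided
by its sample sd, ddof = 1, matching the R `scale()`/`prcomp(scale=TRUE)`
convention) separately for the δ13C and δ15N amino-acid blocks, via an
eigendecomposition of the 10×10 correlation matrix. Two conventions are
fixed for reproducibility where PCA leaves them free:

* **Sign.** Each component is oriented so its largest-|loading| entry is
  positive. Correlations against bulk values are therefore reported with
  the obtained orientation; the magnitude |r| is the meaningful quantity.
* **Contributions.** A variable's contribution to a component is
  100·loading², so each component's contributions sum to 100%.

stdDeltaS is bulk δ34S standardized to mean 0, sample variance 1 over the
complete-case subset. The 1D/2D/3D/5D axis sets are fixed (see README);
axis order is always PC1-Css, PC1-Nss, stdDeltaS, PC2-Css, PC2-Nss
restricted to the approach.

Trophic indices use the conventional glutamic-acid/phenylalanine form
TP = (δ15N_Glx − δ15N_Phe − β)/TDF + 1 with defaults β = 3.4 ‰ and
TDF = 7.6 ‰, both configurable since published calibrations vary by tissue
and taxon. The mean-amino-acid variant uses mean(trophic set) − mean(source
set) with defaults trophic = {Ala, Asp, Glx, Ile, Leu, Pro, Val} and
source = {Gly, Phe, Lys}.

No time-dependent (Suess) baseline correction of δ13C is applied; the
pipeline operates on the values as given. Where a correction matters it
should be applied upstream of the canonical CSV.

## Niche posterior

Per group, with sample mean x̄ and centered sum-of-squares S, the posterior
under π(μ, Σ) ∝ |Σ|^−(d+1)/2 is Σ ~ IW(S, n−1), μ|Σ ~ N(x̄, Σ/n); K
independent draws (default 100 000) are taken with scipy's inverse-Wishart
sampler and a Cholesky transform for μ. The posterior is proper only for
n ≥ d + 2; smaller groups are reported as *not estimable* rather than
silently regularized, because a ridge prior would quietly change the method.

Niche size applies the χ²/Γ ellipsoid-volume formula to each Σ draw.
Directional overlap draws `n_mc` (default 1 000) Monte-Carlo points from the
source group's normal per paired posterior draw and scores them against the
target group's α-ellipsoid (α default 0.95); the per-draw hit fractions form
the overlap posterior. Work is chunked over draws so memory stays flat at
any K. Both the posterior mean and the KDE mode of overlap are reported,
since summaries of a skewed overlap posterior differ.

Posterior summaries: quantiles use the standard linear-interpolation
empirical estimator; modes use a Gaussian KDE with Silverman bandwidth
evaluated on a 512-point grid over the draw range (a constant draw vector
short-circuits to that constant). Niche-size tables report mode with 5% and
95% quantiles; community-metric tables report mean with 2.5% and 97.5%
quantiles.

## Community metrics

Layman metrics are computed per posterior draw on the species' centroid
draws — not on raw data points — so community structure inherits the niche
model's uncertainty. The community centroid is the unweighted mean of
species centroids (Layman's original convention; weighting by sample size
would let archival collection effort move the community centroid). SDNND
uses the population (divide-by-S) standard deviation — with five species the
choice is material and had to be pinned. CD/NND/SDNND are rotation- and
translation-invariant; per-axis ranges are axis-dependent by design.

## Comparison statistics

The Bhattacharyya coefficient bins both draw vectors on 100 equal-width
bins spanning their union range (BC = Σ√(p·q)); shared binning makes it
exactly symmetric, and sensitivity to 50 vs 200 bins is below 0.03 on
smooth posteriors. An all-identical union range returns 1.0 by convention.

The centroid-difference probability splits each group's μ draws into equal
null and test halves using one seeded permutation applied to both groups,
then reports p = P(d_between − d_A,within − d_B,within > 0) across paired
indices. The shared permutation makes self-comparison return p = 0 exactly.
The statistic is conservative by construction: under identical generating
distributions it concentrates near 0.1 rather than uniform, so values above
~0.5 indicate meaningful separation, not frequentist significance at 0.5.
The reported centroid distance is the mean over paired draws of
‖μ_A − μ_B‖₂.

The temporal analysis fixes the period split (defaults 1970–1989 vs
1990–2006, inclusive) and builds the dimension spaces once on the full
complete-case dataset so both periods share one PCA basis — refitting per
period would make centroid shifts unidentifiable. Each period then gets its
own posterior, sizes, both overlap directions, and the comparison
statistics. An approach failing the n ≥ d + 2 precondition in either period
is flagged and the others proceed.

## Synthetic-data generator

The generator is the package's study system. Five latent axes — carbon
source, a secondary carbon axis, nitrogen baseline, trophic enrichment,
sulphur — carry species-specific multivariate-normal positions; a fixed
21×5 loading map projects them onto the tracers with 0.5 ‰ additive
Gaussian measurement noise. Amino-acid δ13C loads near-uniformly on carbon
source with proline dominating the secondary carbon axis; amino-acid δ15N
loads near-uniformly on the baseline axis, with the trophic amino acids
(Ala, Asp, Glx, Ile, Leu, Pro, Val) also loading on the trophic axis and
the source amino acids (Gly, Phe, Lys) essentially not. Bulk δ13C/δ15N are
uniform-weight amino-acid means plus 0.3 ‰ noise, so PC1 of each block is a
planted proxy for the bulk value. Intercepts sit at realistic egg-tissue
values (amino-acid δ13C −26…−18 ‰, δ15N 6…18 ‰, δ34S ≈ 17 ‰).

The packaged community has five species and 63 samples (20/15/10/9/9 —
per-species allocation is a configurable guess at an uneven archival
collection): a storm-petrel-like species isolated on the nitrogen baseline,
two alcid-like species separated from each other only on carbon source and
sulphur, and two cormorant-like species close on every axis, the generalist
with the widest covariance. Both cormorant-like species carry a post-1990
centroid shift concentrated on the carbon axes plus a covariance shrink
(scale 0.7 and 0.4), emulating a prey-base decline; period membership is
derived from the sampled year (uniform over the species' year range) at
analysis time, not at generation time.

What the generator does **not** emulate: non-normal or skewed niche shapes,
temporal autocorrelation within a period, inter-laboratory offsets,
tissue-specific fractionation, pooling variance structure, or any
mechanistic food-web dynamics. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the multivariate-
normal model it assumes — not that real niches satisfy that model.

## Numerical choices

* Inverse-Wishart sampling via scipy (Bartlett-style, Cholesky-based);
  determinism comes from a `numpy` Generator seeded per stage, with child
  seeds derived from one pipeline seed through `SeedSequence`.
* Overlap Monte-Carlo uses 1 000 points per draw by default — at K = 10⁵
  the posterior-mean overlap has standard error below 10⁻³, and halving or
  doubling `n_mc` trades variance for runtime linearly.
* Degenerate inputs fail loudly: zero-variance tracer columns name the
  offending amino acid, non-positive-definite covariances are rejected, and
  empty complete-case sets raise.
* Volumes are computed through `det`/`log` in d ≤ 5 where conditioning is
  benign; niche sizes are validated against rejection sampling in the test
  suite.

## Problem sizes

The test suite and the acceptance script run the same machinery at reduced
but statistically meaningful sizes — K of 2 000–20 000 posterior draws,
500–10 000 Monte-Carlo points, 50-replicate calibration loops — chosen so
each check's tolerance is dominated by the statistic's own sampling error,
not by the budget. The pipeline default remains K = 100 000.

## Limitations

* Niche-size magnitudes in high d are sensitive to the ellipsoid-volume
  formula's steep χ²^(d/2) growth; cross-dimensional size comparisons
  should be read as ordinal, and high-d hypervolumes interpreted with
  caution.
* The nearest-neighbour metrics (NND/SDNND) are computed on centroid draws;
  definitions computed on raw data points would give different magnitudes.
* The centroid-difference probability is conservative and has no uniform
  null distribution; it is a descriptive posterior summary, not a p-value.
* Complete-case filtering can bias a community summary if missingness is
  structured by species or era.
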