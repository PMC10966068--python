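# Methods

`asymkit` implements a case-control analysis of structural brain
asymmetry for carriers of recurrent copy-number variants (CNVs):
deletions and duplications at the 1q21.1 distal, 15q11.2 BP1-BP2,
16p11.2 proximal and 22q11.2 proximal loci.  This note describes the
model and procedures, the tunable parameters, what the synthetic data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Asymmetry index

For each of 65 homologous region pairs (48 cortical, 7 subcortical, 10
cerebellar; 130 gray-matter volumes per subject), the asymmetry index is

    AI = (L − R) / ((L + R) / 2)

with L, R the left and right regional volumes.  AI is dimensionless,
bounded in (−2, 2) for positive volumes, scale-invariant, and positive
for leftward asymmetry.  Before AI computation, volumes are adjusted
for scanning site by removing per-(region, hemisphere) site means
(least squares on site indicators, grand mean retained), fitted jointly
on all subjects.  Joint fitting can leak group signal into site
estimates when sites are group-imbalanced; the generator assigns sites
uniformly, and real-data users should check balance.  Age, sex and
intracranial volume are deliberately **not** regressed out of AI; a
separate covariate-adjustment path (`covariate_adjust_volumes`:
ICV, age, age², sex, site) exists only for the raw-volume effect-size
analyses.  Sample SD (n−1) is used in every z-scoring and effect-size
computation; the package standardises on this convention throughout.

Two z-scoring modes serve different consumers: `control_z` (per-region
control mean/SD) for descriptive group tests, and `pooled_z` (mean/SD
over the subjects entering a model fit, i.e. one carrier group plus
controls) before discriminant learning.

## Discriminant patterns

The carrier-vs-control pattern is the linear discriminant direction

    w ∝ Σ̂⁻¹ (μ̂_case − μ̂_control)

on pooled-z asymmetry indices.  Σ̂ is the pooled within-class
covariance shrunk toward its diagonal, Σ̂(λ) = (1−λ)S + λ diag(S), with
λ chosen analytically (Schäfer–Strimmer: λ* = Σ_{i≠j} Var̂(s_ij) /
Σ_{i≠j} s_ij², clipped to [0,1]).  Shrinkage matters because 65
features meet as few as 22 carriers; a diagonal target is natural for
z-scored features.  λ can also be fixed by the caller.  Coefficients
are canonically oriented so they correlate non-negatively with the
per-region Cohen's d map (ties keep the fitted sign), resolving the
reflection invariance of discriminant axes.  In-sample discriminant
scores give a rank-statistic (Mann–Whitney) AUC with tied scores
counted half-concordant; a cross-validated AUC was considered and left
out of scope since the pattern itself — not out-of-sample prediction —
is the object of interest.

### Bootstrap significance

Coefficient robustness is assessed over B = 1000 refits on cohorts
resampled with replacement at the original sample size, stratified
within class so both classes are always present (an unstratified mode
is available; draws missing a class are then redrawn).  Each draw's
coefficient vector is multiplied by ±1 to correlate non-negatively with
the full-sample Cohen's d map; a region is significant when the aligned
2.5/97.5% percentile interval excludes zero.  The pooled-z transform is
applied once to the full two-class sample and bootstrap draws resample
rows of the scaled matrix without re-scaling: the CIs then describe the
variability of the pattern fitted to the scaled data the full-sample
coefficients live in.  Degenerate draws (singular covariance) are
redrawn and counted.  Under null simulations the per-region flag rate
sits near the nominal 5% (the package's acceptance suite checks the
2–9% band over 50 replicate cohorts).

### Multiclass model

A single discriminant model over all eight carrier groups solves the
eigenproblem of the within-class-whitened between-class scatter
(Cholesky whitening by the same shrunken pooled covariance), yielding
K−1 = 7 axes ordered by decreasing between/within variance ratio; the
two leading axes expose the regions that most separate the CNVs.  With
two classes the single axis is collinear with the two-class direction,
which the tests assert.

## Univariate effects

Cohen's d uses the average-variance denominator,
d = (x̄₁ − x̄₂) / √((s₁² + s₂²)/2), with a stratified percentile
bootstrap (B = 1000, 2.5/97.5%) for CIs.  Per-hemisphere volume effects
are computed on covariate- or site-adjusted raw volumes — never on AI.
Group tests on control-z AI are Welch two-sided t-tests (the
unequal-variance form is the safer default for unequal group sizes; a
Student option exists) with Benjamini–Hochberg FDR across the 65
regions of one contrast.  Pooling the FDR family across contrasts is
available via the shared BH routine but is not the default.

## Spin-permutation pattern comparison

Pairwise Pearson correlations between coefficient maps are tested
against a spatial null that preserves each map's spatial structure.
Cortical parcels are reassigned by nearest-centroid lookup under
uniformly random 3-D rotations (sampled as normalised quaternions, so
exactly uniform on SO(3)) of the left-hemisphere spherical centroids;
the mirrored (x-flip conjugate) rotation governs the right hemisphere
and, for the hemisphere-symmetric packaged atlas, yields the identical
assignment — asserted as an invariant.  Spherical rotation has no
geometric meaning for subcortex and cerebellum, so those parcels are
permuted uniformly within tissue class.  Nearest-centroid ties break to
the lowest region index.  Empirical p-values are two-sided with add-one
smoothing, p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_spin), so p ≥
1/(n_spin+1) and never 0.  Pattern sets are summarised by Ward
hierarchical clustering on Euclidean distances between raw coefficient
vectors (correlation-distance clustering was considered; Euclidean on
like-scaled coefficients keeps merge heights interpretable).

## Functional decoding

Correlation mode maps the 65 coefficients onto both hemispheres as
absolute values and Pearson-correlates the 130-unit map with each
term-activation map.  Binned mode uses the signed bilateral map
(original coefficients on the right hemisphere, opposite sign on the
left), ranks the 130 units and partitions them into 20 five-percentile
bins whose sizes differ by at most one unit, with the larger bins
placed symmetrically at both ends so that negating the map reflects the
binning exactly (location L → 21 − L).  Per term, the mean activation
per bin is z-scored within term; bins with z < 0.5 are zeroed; the
per-bin weighted score is the thresholded (z-valued) activation times
the bin's mean coefficient; the term's location is the score-weighted
mean bin index.  Within-bin aggregation uses the mean (scale-stable
across unequal bins); whether the coefficient factor should be a bin
mean, median or rank was open — the mean keeps the score linear in the
coefficients.  The procedure operates at parcel level because its
inputs are parcel values; denser unit tables (e.g. vertex data) pass
through unchanged.

## Synthetic data generator

The generator's defaults are the study conditions: 290 controls and
552 carriers (32/27 at 1q21.1 del/dup, 110/144 at 15q11.2, 82/69 at
16p11.2, 66/22 at 22q11.2), ages 6–64, 56% male, three scanning sites.
Volumes are lognormal — positivity guarantees a valid AI denominator —
with mean 5000 volume units, coefficient of variation 0.12, and
within-pair L/R correlation 0.9 in log space, giving a control AI SD of
about 0.05, a realistic spread for regional gray-matter asymmetries.
Per-region volume variances are stipulated, not matched to any
empirical table (none is available).  Site effects are additive
per-(region, hemisphere) constants with SD 150 — exactly the model the
site-adjustment step removes.  Planted group effects are AI shifts in
control-SD units, realised by scaling the left volume by 1 + f with
f = 2δ/(2 − δ) (exact for a symmetric pair; the residual bias is second
order in the log-volume SD), where δ converts the shift via the control
group's empirical offset-free AI SD.  Left-only planting mirrors the
left-dominant effects this kind of cohort shows; right-sided and
split-sided planting are configurable.  The default effect map touches
the regions most implicated in CNV asymmetry studies — planum
temporale (increased asymmetry for 16p11.2del, 22q11.2del, 15q11.2dup;
decreased for 1q21.1del), temporal fusiform cortex, parahippocampal
gyrus, parietal operculum, cuneal and supracalcarine cortex, putamen,
cerebellar lobule VIIIb — with magnitudes of 0.3–1.0 control-SD chosen
once as plausibly large monogenic effects.

What the generator does **not** emulate: covariate–volume confounding
(age/sex do not influence volumes, so covariate adjustment is exercised
only as a no-op plus planted-signal tests), spatially correlated
region-to-region covariance (regions are independent given the L/R
pairing, which makes diagonal shrinkage optimal by construction),
non-additive or scanner-specific site effects, and any genotype
structure.  Passing tests therefore certify the pipeline's statistical
machinery — calibration, power, determinism, oracle agreement — not its
behaviour under real-data covariance or harmonisation challenges.

Term-map fixtures are Gaussian noise tables with optional planted
signal terms; they stand in for meta-analytic activation databases,
which the package deliberately neither downloads nor redistributes.

## Determinism and problem sizes

Every stochastic step takes an explicit integer seed; pipeline stages
derive independent substreams from one root seed via `SeedSequence`,
and reruns with an identical configuration reproduce every output file
byte-for-byte (TSV floats are written at 10 significant digits).  The
acceptance suite runs its calibration studies at moderated sizes chosen
to keep Monte-Carlo error well inside the tested bands: 50 null cohorts
(n = 60/200, B = 1000) for bootstrap calibration, 25 seeds for power,
200 replicates at n_spin = 1000 for spin-test uniformity, 20 seeds for
decoding recovery.

## Known limitations

- In-sample AUC overstates out-of-sample separability, especially for
  the smallest carrier groups; treat it as a descriptive fit index.
- Percentile bootstrap CIs for shrunken LDA coefficients are
  approximate; the null flag rate is near, not exactly, 5%.
- The spin null permits duplicate assignments (some parcels sampled
  twice, others dropped), the standard behaviour of
  centroid-rotation nulls at parcel resolution.
- Site adjustment assumes additive site effects; scanner-specific
  scaling or variance differences call for harmonisation tools outside
  this package's scope.
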