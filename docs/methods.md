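# Methods

This note documents the models, algorithms and numerical choices behind
`erqc`, and what the synthetic data used for validation does and does not
establish about real slides.

## Optical density and color deconvolution

Brightfield chromogens attenuate light multiplicatively, so all
quantification happens in optical density, `OD_c = −log10(max(I_c, 1)/I0)`
per channel, with an 8-bit white point `I0 = 255` and intensities clamped to
≥ 1 so ODs stay finite (capping representable OD at ~2.41 per channel).
Log base 10 follows the Ruifrok–Johnston convention the stain vectors come
from.  The inverse transform quantizes to whole intensity levels, and the
round trip is the identity to ±1 level.

Stain unmixing solves `Mᵀc = od` per pixel, where the rows of `M` are unit
OD-space vectors for hematoxylin, DAB and a residual channel.  The default
vectors are the Ruifrok–Johnston H-DAB pair — hematoxylin (0.65, 0.70,
0.29), DAB (0.27, 0.57, 0.78), each normalised — with the residual row
completed as their normalised cross product, making `M` well conditioned by
construction.  Negative solutions (possible under noise) are clamped to
zero after solving, and the worst-case reconstruction residual of the
clamped solution is carried on the result for audit.

Slide-specific vectors can instead be estimated from the image by
plane/percentile (Macenko-style) estimation: pixels with total OD below a
floor β (default 0.15) are discarded as unstained, the remainder are
projected onto the plane of the two leading singular directions of the OD
cloud, and the α-th / (100−α)-th percentile extreme angles (α = 1%) are
taken as the stain pair.  Estimation refuses (and callers fall back to the
defaults) when fewer than 100 pixels pass the OD floor.  Identity
assignment uses the blue-minus-red OD component: hematoxylin is a blue
counterstain, so it absorbs mostly red/green (small blue OD component),
while DAB is brown and absorbs mostly blue — the estimated vector with the
smaller blue−red component is therefore hematoxylin.  The estimator is
deterministic and invariant to image rotation and pixel permutation; with
noiseless two-stain composites containing some near-pure pixels it recovers
the generating vectors to well under 1°, and to about 4–5° under 0.02-OD
Gaussian noise (the percentile extremes overshoot slightly under noise;
very weakly stained pixels near the OD floor carry most of the angular
error).  Per-image estimation is the default; a per-slide matrix can be
estimated once and passed to every region.

## Nucleus detection and exclusion rules

Detection runs on the unmixed maps inside each annotated duct polygon.
Nuclear foreground is the set of pixels whose raw total (H + DAB) OD *and*
whose Gaussian-smoothed total OD (σ = 1.5 µm) both reach the threshold
(0.1 OD), cleaned by a 1-pixel binary opening.  The two conditions play
different roles: the raw condition keeps object outlines sharp, while the
smoothed condition and the opening suppress isolated noise speckle.
Thresholding only the smoothed image was rejected during development
because a threshold far below the nuclear OD plateau dilates every object
by several pixels — inflating areas roughly two-fold (enough to trip the
merged-object exclusion) and fusing neighbouring nuclei into blobs with a
single distance-transform peak that the watershed cannot split.

Seeds are local maxima of the Euclidean distance transform separated by at
least 4 µm; a seeded watershed on the negated distance transform splits
touching nuclei.  Per object we measure pixel area (µm²), the
marching-squares boundary polygon, perimeter as that polygon's length,
circularity `4π·area/perimeter²` clamped to [0, 1] (rasterisation can push
the raw value slightly above 1 for small disks), and mean hematoxylin and
DAB amounts over the object's pixels.  Objects whose centroid falls outside
the polygon are discarded; objects touching the boundary with an inside
centroid are kept.

Three exclusion rules, evaluated in order with first match winning,
automate the manual curation step of watershed output:

1. **merged** — area ≥ 2.0 × the nominal luminal nucleus area (40 µm²);
   the boundary is inclusive (exactly two nuclei's area is merged);
2. **fragment** — area < 0.5 × nominal;
3. **non_nucleus** — circularity < 0.55.

All thresholds sit in `DetectionParams` and are deliberate, configurable
stand-ins for per-region manual tuning; codes are logged per object for
audit.  On rendered fixtures with non-overlapping nuclei and 0.02-OD noise
the detector achieves ≥ 95% recall and precision and recovers assigned
mean nuclear DAB to within 5%.

Detection runs on the total (H + DAB) OD rather than hematoxylin alone so
that strongly DAB-positive, hematoxylin-weak nuclei are still found; this
is a package choice, not a claim about any particular reference pipeline.

## ER quantification

A retained nucleus is **positive** when its mean nuclear DAB OD reaches
τ = 0.10 (boundary inclusive).  The 0.10 default is a conventional DAB
positivity floor; no published threshold exists for the assay this mirrors,
so τ is explicit in the configuration and in all validation runs.  A duct
needs at least 2 positive nuclei for a defined dynamic range
`(max − min) × 100`; below that the duct is invalid and its DR is reported
as missing.  The ×100 scaling applies to the DR statistic only; raw
per-nucleus ODs are stored unscaled.  Case summaries (median and range of
DR) are computed over valid ducts only, and a case with none is flagged
uninterpretable — the analogue of excluding cases without internal control
epithelium.  Cohort-level medians are taken over all valid ducts pooled
across cases; per-case summaries are also computed, since which pooling the
published medians used is not stated.

`qc_flag` operationalises the clinical recommendation: a case whose median
DR falls below the 5th percentile (configurable) of a reference
distribution of control-case medians is flagged with the recommendation to
repeat ER IHC testing.

## The mixed model

Ducts from one patient are correlated, so cohort comparisons model the
log-transformed response (natural log; the base only rescales β) with a
per-case random intercept and a varPower residual:

    ln y_ij = β₀ + β₁·1[cohort_i = contrast] + b_i + ε_ij
    b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ²·|v_ij|^(2δ))

with `v_ij` the duct's positive-cell count — a mean OD built from few
nuclei is noisier, and δ (typically negative) lets the model say so.

Estimation is maximum likelihood, not REML, so the likelihood-ratio test
across variance structures and AIC comparisons are coherent; δ is free
(not boundary-constrained), so the 1-df χ² reference for the LRT is the
regular one.  β and σ² are profiled out in closed form by generalized least
squares given `(θ = σ_b²/σ², δ)`; each case block's inverse and determinant
use the Woodbury/matrix-determinant identities, so a likelihood evaluation
is O(N).  The profiled log-likelihood is maximised by bounded L-BFGS-B over
`(ln θ, δ)` with ln θ ∈ [−20, 10], δ ∈ [−3, 3], from five starts (a moment
start for ln θ — half the between-case variance of case means over the
within variance — with offsets ±2, and δ ∈ {0, ±0.5}); numerically singular
corners of the bounds return a large penalty.  With one duct per case the
profile is flat in θ (σ_b and σ are then not separately identifiable); β,
the likelihood and all inference remain well defined on the ridge.

Inference for β₁ defaults to a Wald *t* statistic with `N − 2` degrees of
freedom and the bias-corrected residual scale `RSS/(N − 2)`.  This choice
makes the model collapse *exactly* to the pooled two-sample t-test when
δ = 0 and each case contributes one duct, and is mildly conservative
relative to a normal reference otherwise; a plain normal-reference Wald
test (`inference="normal"`) is available.  Note `N − 2` counts
observations, not cases, so with many ducts per case the stated df
overstates the effective information — the package's p-values at the
study's design are dominated by effect size, not by this approximation,
and the fit exposes everything needed for other df rules.

`select_variance_structure` compares the δ = 0 fit with the free-δ fit:
the alternative is chosen when the LRT rejects at 0.05, otherwise the
lower-AIC fit wins (AIC = −2·logLik + 2k, k = 4 or 5 estimated
parameters).  An alternative log-likelihood below the null beyond 1e-6 is
reported as an optimisation failure rather than silently accepted.

Validation: the fitted likelihood agrees with a dense multivariate-normal
evaluation to < 1e-6 and with R `nlme::lme(weights = varPower(...))` — the
canonical implementation of this model family — to ~1e-3 in log-likelihood
on shared data; a full-likelihood Nelder-Mead search cannot improve the
profiled optimum by more than 1e-4; parameter recovery at a 40-case × 10-duct
design is within 10% for β₁, σ_b and δ; and the LRT's type-I error is
consistent with 5% over 500 null replicates.

The classical auxiliary tests (pooled-variance Student's t, Fisher's exact
with the two-sided point-probability rule, Spearman with mid-ranks and the
n−2-df t approximation) are delegated to scipy behind a uniform result
type, with brute-force enumeration/permutation oracles kept in the test
suite.  The Spearman t approximation tracks the exact permutation p-value
to about 0.02 for clear monotone association at n = 6 but can deviate by up
to ~0.05 for mid-range correlations at such small n; at the duct counts
this package analyses (dozens to hundreds) the approximation error is
negligible.  Degenerate inputs are explicit: zero pooled variance yields
p = 1 (equal means) or p = 0; a constant sample makes the correlation
undefined and raises.

## Synthetic cohorts and calibration

`simulate_cohort` draws, per case, `b_i ~ N(0, σ_between²)` and a uniform
duct count; per duct, a uniform positive count `v` and residual
`e ~ N(0, σ_within²·v^(2·δ_gen))`; the response is
`exp(μ + b_i + e)`.  δ_gen defaults to 0 — heteroscedastic generation is
reserved for the varPower recovery tests, since no fitted δ is published.
Randomness is hierarchical (`SeedSequence` substreams per case and duct),
so tables are bit-reproducible and stable under partial regeneration.

The three default cohort specs fix everything the published summaries pin
down: cohort sizes 21 / 34 / 10; ducts per case 2–24, 2–30, 2–10; positive
counts per duct 7–90, 3–182, 2–51; and log-scale locations ln 16.5,
ln 30.8, ln 114 (the published pooled DR medians).  The split of the
log-scale spread between case and duct level is *not* published; the
defaults — low-ER (0.25, 0.87), control (0.35, 0.95), TMA (0.15, 0.37) —
were fixed once by a Monte-Carlo calibration requiring (a) the pooled
per-duct median within ±20% of its target in ≥ 95% of replicates and
(b) the published range endpoints inside the pooled 0.1st–99.9th percentile
band.  Both criteria pull on the same two constants in opposite directions
(a tighter spread concentrates the median but shrinks the extremes), and
the shipped values satisfy both with margin.  They remain honest stand-ins:
matching printed medians and ranges does not mean the real between-case
correlation structure is matched, so mixed-model results on synthetic
cohorts validate the machinery, not the clinical effect size.

`render_duct` paints hard-edged disk nuclei (radius 3.5 µm ± 10% jitter,
rejection-sampled without overlap) into an annulus (inner 30 µm, outer
50 µm at 0.5 µm/px), assigns each nucleus a hematoxylin OD uniform in
[0.4, 0.8] and a prescribed DAB OD, composites through the stain matrix
over a faint counterstain background (0.05 OD), adds pixelwise Gaussian OD
noise (sd 0.02), and converts to RGB.  `render_cohort_images` back-solves
per-nucleus DAB assignments from each simulated duct's DR — minimum
anchored at τ + 0.02, maximum at min + DR/100, capped at a physical 3.0 OD
with a warning, remaining nuclei uniform between — so end-to-end ground
truth is exact up to the stated clipping.  The renderer makes no attempt at
photorealism (no texture, stroma, lumen debris, overlapping chromatin), so
pipeline performance on rendered ducts bounds segmentation difficulty from
below; real slides will need per-cohort parameter review.

## Problem sizes in shipped checks

Validation runs are sized for a single CPU: cohort-calibration sweeps use
20 seeded replicates per cohort (the release calibration itself used
400–1000), mixed-model recovery uses 200 replicates of the 40×10 design,
LRT calibration 500 null replicates, and rendered-image checks a handful
of ducts with 12–15 nuclei.  The acceptance script recomputes the headline
quantities with 20 replicates per number and finishes in seconds.

## Known limitations

- Exclusion rules are fixed thresholds standing in for manual curation;
  they inherit none of a pathologist's context.
- The watershed has no shape prior; heavily overlapping nuclei beyond the
  rendered regime will merge or fragment.
- The Wald df rule is a pragmatic approximation (see above); Satterthwaite
  or Kenward–Roger style corrections are not implemented.
- Stain estimation assumes exactly two dominant chromogens; necrosis,
  pigment or mounting artefacts violate the plane model.
- No stain normalisation across slides is attempted; cross-slide OD
  comparability rests on the shared staining protocol, as in the underlying
  study design.
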