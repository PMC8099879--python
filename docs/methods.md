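# Methods

This note documents the models, estimators, numerical choices and
known limitations of the package, module by module.

## Localization (sCMOS MLE with CRLB)

Raw frames (ADU) are converted to photoelectrons with per-pixel
calibration maps (offset, gain, read-noise variance).  The compound
per-pixel noise — Poisson shot noise convolved with Gaussian read
noise — is handled with the standard variance-offset device: the
read-noise variance in e⁻² is added to both the data and the model
expectation, after which the likelihood is treated as Poisson.  Each
candidate (local maximum of the raw-minus-lowpass image above 4×
robust noise sd; lowpass = inverse-variance-weighted box filter of
width 4×FWHM) is fitted in a 7×7 window by L-BFGS-B with analytic
gradients; free parameters are (x, y, photons, background) with the
PSF sd fixed from the configured FWHM.  The reported precision is the
CRLB from the Fisher information at the optimum,
I_ab = Σ (∂μ/∂a)(∂μ/∂b)/(μ + var/g²).

Multi-emitter windows are handled by rejection rather than multi-PSF
fitting: windows whose reduced residual (χ²-like, Poisson-normalized)
exceeds 3 are dropped, as are fits below a 100-photon floor or without
convergence.  Optimizer budget: 400 iterations, gradient tolerance
1e-8; the budget matters — an early-terminated fit leaves photons and
background correlated and under-estimated.

**Blink merging.**  Localizations of one channel appearing in
consecutive frames within 2.5× the candidate's own precision of the
running inverse-variance-weighted mean collapse to one record
(positions by inverse-CRLB-variance weighting, merged variance
1/Σ(1/varᵢ), photons summed, multiplicity = chain length).  Merging is
defined on frame-resolved raw records; a record with multiplicity > 1
is a completed blinking event and passes through unchanged, which
makes the operation exactly idempotent.  The skew-Gaussian fit of the
precision distribution is quality-control reporting only; no filtering
is derived from it.

## Registration

Channel maps are degree-2 polynomials over {1, x, y, x², xy, y²}
fitted by least squares to mutually-nearest bead pairs within a 500 nm
capture radius (ambiguous beads dropped).  Coordinates are centered
and scaled by the maximum absolute deviation before the solve for
conditioning; rank deficiency (e.g. collinear bead layouts) raises.
Because the quadratic basis nests the affine one, the fitted residual
can never exceed an affine-only fit's — this is property-tested.

## Pair correlation

g(r) is estimated by direct pair counting (KD-tree cumulative
neighbor counts): reference points are restricted to the ROI eroded by
r_max so that every annulus lies fully inside the ROI, while the
density normalizer ⟨ρ⟩ uses the full ROI.  One self-pair per reference
point is excluded; genuinely coincident pairs are kept.  The
un-centered normalization ⟨ρρ⟩/⟨ρ⟩² (CSR baseline 1) is used so the
estimator matches the "+1" baseline of the fitted model.

The two-Gaussian fit fixes ⟨ρ⟩ to the observed count/area (otherwise
the first-term amplitude is degenerate with A), weights bins by
1/√(pairs+1), and excludes the first bin (self/merge artifacts).
Bounds: σ ∈ [0.5, 200] nm, A ≥ 0 (a fit pinned at zero is flagged),
r_app ∈ [1, max(500, r_max)] nm.  The first model term is only
identified when the data contain stochastic re-sampling of the same
molecule (blinking overcounts); on merged single-visit data σ is
unidentified and the synthetic generator therefore emulates
re-localization multiplicity.

**Content convention.**  The content formula ⟨N⟩ = 2π⟨ρ⟩A·r_app²
integrates a Gaussian of sd r_app although the correlation term it is
derived from has width 4(σ² + r_app²).  Its expectation on a field of
Gaussian foci with N localizations each is therefore

    E[⟨N⟩] = N · f_clustered · r_app² / (2 (σ² + r_app²)) ≈ N/2,

where f_clustered is the clustered fraction of all localizations.  The
width-consistent count 4π⟨ρ⟩A(σ² + r_app²) recovers N directly.  The
package reports the first (the identity ⟨N⟩ = 2π⟨ρ⟩A r_app² holds to
machine precision for every fit result) and the test suite verifies
both relationships; users comparing absolute contents across tools
should be aware of the factor ≈ 2 between the conventions.

## Triple correlation

The TC function is computed exactly as a coordinate-visiting estimate:
for every channel-1 point in the ROI eroded by r_max, the channel-2
and channel-3 density fluctuations δρ = count/area − ⟨ρ⟩ are estimated
in sector-annulus bins (area r·Δr·Δθ with Δθ = 2π/n_theta; defaults
Δr = 20 nm, r_max = 300 nm, n_theta = 18), their products formed at
every (r₁ bin, r₂ bin, angular-offset) cell, averaged over visits and
orientation, and normalized by ⟨ρ₂⟩⟨ρ₃⟩ (visiting channel-1
coordinates weights by ρ₁, so the ⟨ρ₁⟩ factor of the definition
cancels; the small centered-numerator correction ⟨ρ₁⟩⟨δρ₂δρ₃⟩ is not
subtracted, matching the coordinate-visiting description of the
statistic).

**Geometry collapse.**  A circular shift of d angular bins corresponds
to an exact offset φ = d·Δθ between the two sampling directions.  The
rotation-invariant grid uses the transform
r₃² = r₁² + r₂² + 2r₁r₂cos(Δθ) with Δθ = π − |φ|, i.e. the transform's
angular variable is the supplement of the sampling-direction offset —
with this convention r₃ equals the physical channel-2/channel-3
distance, and an equilateral pattern (vertex angle 60°) lands at
r₃ = r₁ = r₂.  Species-exchange symmetry (swapping channels 2 and 3
transposes the collapsed grid) holds exactly and is property-tested.

**Significance.**  Nulls resample the probe channel (channel 3) as CSR
at matched density, preserving channel-1/2 structure.  Because the
grid holds thousands of cells, per-cell z ≥ 3 alone cannot control the
scene-level false-positive rate; the detection threshold is therefore
raised to the k-th order statistic of the null ensemble's own
leave-one-out maximum-z values with k = ceil((1−α)(n_null+1)) — by
exchangeability of the observed map with the nulls this controls the
family-wise error at exactly α (default 0.05).  With 20 nulls the
threshold is the null maximum (exceedance 1/21); 39 nulls allow the
second-largest (2/40), which is robust to a single outlier null and is
used where detection power matters.  Two stabilizations apply to both
detection and calibration: the innermost radial bin of r₁/r₂ is
excluded (its sector area is so small that a single chance count
yields δρ/⟨ρ⟩ in the hundreds — the analog of the first-bin exclusion
in the g(r) fit), and cell sds are floored at a quarter of the median
positive cell sd.  Detected cells are grouped into connected
above-threshold regions; each region reports one triplet at its mode
cell (largest z, ties broken by smaller r₁+r₂+r₃).

**Conditional density.**  C₃ = ⟨δρ₁δρ₂δρ₃⟩/⟨δρ₁δρ₂⟩ is evaluated at a
triplet's cells from the same visit-averaged arrays: the numerator is
the unnormalized fluctuation product averaged over the angular cells
mapping into the triplet's r₃ bin, the denominator the visit-averaged
channel-2 fluctuation at the r₁ bin.  It is insensitive to uniform
channel-3 background (a fluctuation statistic) and scales linearly
with the per-site channel-3 occupancy; both properties are tested.

**Pattern frequency.**  The frequency of a significant pattern is the
exhaustive (O(N₁N₂N₃)) instance count at the detected geometry
(tolerance one grid bin) divided by a co-analyzed reference-pattern
count supplied by the caller; no absolute normalization is implied.

## Cluster colocalization

DBSCAN with eps 15 nm and min 3 points segments foci; noise points are
retained with labels.  "Edge-to-edge" NND is the distance between
cluster boundaries, realized as convex hulls (degenerate 1–2-point
clusters fall back to the point/segment geometry); overlapping hulls
have distance 0.  Pairs within 5 nm are colocalized; fractions are
reported per direction (colocalized clusters of a species over its
cluster count).  The randomized baseline rigidly translates every
cluster of the second species to a uniform ROI position with a uniform
rotation, rejection-sampled to keep it wholly inside the ROI, and
recomputes the fraction (default 100 iterations); the observed
fraction is summarized as a z-score against this baseline.

## smFRET

Efficiency is E = a/(a+d) clipped to [0, 1]; frames whose total
intensity falls below 10% of the median total are masked as
dark/bleached.  The pooled histogram (50 bins on [0, 1]) is fitted by
two independent Gaussians seeded from the low- and high-half peaks;
the unfolded fraction is the low-E component area over the total area
(component areas, not a hard cut, so heavily overlapping populations
degrade gracefully and a collapsed fit is flagged).  Idealization uses
a two-state Gaussian-emission hidden Markov model (EM-trained on the
pooled sequences, deterministic given its histogram-peak
initialization) with Viterbi paths; a midpoint threshold is the
fallback if EM degenerates.  Dwell times exclude the first and last
dwell of every trajectory (censored); rates are exponential maximum
likelihood on the dwell durations, k = 1/mean with sd k/√n from the
Fisher information.  k_unfold comes from folded-state dwells, k_fold
from unfolded-state dwells.

## Synthetic data

The generators define the study conditions used by every recovery
test:

- **Camera frames**: pixel value = offset + gain·Poisson(μ) +
  N(0, read sd); μ integrates each emitter's photons over the pixel
  under the 2D Gaussian PSF.  Calibration maps draw offset
  100 ± 2 ADU, gain 2.0 ± 0.05 ADU/e⁻, read noise 1.5 e⁻ rms —
  typical sCMOS values.
- **Triplet scenes** (defaults): 6 × 6 µm ROI, 50 triplets at the
  configured pairwise geometry, orientation uniform on [−π, π) with
  random reflection, centroids uniform in the ROI eroded by the
  pattern radius plus 3 sd of scatter (planted patterns never straddle
  the boundary, keeping ground truth exact for oracle tests);
  Poisson(8) molecules per site scattered with sd 10 nm, detection
  efficiency 0.8, localization jitter 10 nm, CSR background
  20 µm⁻²/channel.  None of the multiplicities or efficiencies are
  experimentally established values; they are field-realistic defaults
  intended for sensitivity scans.
- **Cluster fields** (for g(r) recovery): cluster centers uniform on
  the full ROI with toroidal wrap, so the process is statistically
  homogeneous (no boundary depletion bias in the g(r) tail); optional
  re-localization multiplicity (1 + Poisson) emulates blinking
  overcounts.
- **smFRET movies**: the hidden state is an exact two-state
  continuous-time Markov chain sampled at frame starts (sojourns are
  exact exponentials, so ground-truth dwells can be tested
  distributionally); acceptor mean E·I, donor mean (1−E)·I,
  independent Gaussian channel noise.  Defaults: 800 frames at 30 ms,
  E_folded = 0.70, E_unfolded = 0.25, total intensity 1000
  photons/frame, channel noise 90 photons (≈ 0.07 sd in efficiency
  units).

What the generators do **not** emulate: drift, astigmatic/3D PSFs,
full blinking photophysics (only per-frame detection thinning and
optional re-localization multiplicity), spectral crosstalk,
donor/acceptor bleaching (beyond masked dark frames), and any
cell-to-cell biological variability.  Passing recovery tests therefore
demonstrate estimator correctness under the stated statistical model,
not robustness to every real-data artifact.

## Problem sizes

The validation suite runs at desk scale by design: correlation scenes
of ~2–7×10³ points, TC scenes of ~200–10³ points per channel with
20–39 null maps, 12 CSR replicate scenes for the type-I check, 500
localization fits, and 200-trajectory smFRET round trips.  The
acceptance script simulates 200 × 800-frame trajectories.

## Known limitations

- Single-emitter fitting with crowding rejection, not true multi-PSF
  fitting; dense scenes lose overlapping emitters.
- The CSR-resampling TC null preserves channels 1–2 but not
  channel-3 clustering; on strongly clustered probe channels it can
  flag secondary geometries beyond the planted one (each still passes
  the brute-force excess oracle).  A toroidal-shift null is available
  as an alternative for pairwise statistics.
- The max-statistic family-wise calibration is conservative per scene
  (it targets "any false triplet anywhere"); per-cell inference at
  z ≥ 3 remains available via `fwer_alpha=None`.
- Dwell-time rates ignore the frame-discretization bias
  (≈ k·Δt/2 relative, ~1.5% at k = 1 s⁻¹ and 30 ms), which is well
  below the estimator's sampling error at the tested sizes.
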