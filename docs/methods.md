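# Methods

This note records the models, conventions and numerical choices behind
`perisoma`, and what the synthetic-data experiments do and do not show.

## Coordinate and mesh conventions

All geometry lives in world micrometres with axis order (z, y, x), the
origin at the volume corner and voxel centres at (i + 0.5)·spacing. The
default grid is 0.5 µm z-steps with 0.2 µm in-plane sampling, the common
confocal regime for this kind of stack. Surfaces are marching-cubes
iso-surfaces of each binary label at the 0.5 level after a light Gaussian
pre-smoothing of the indicator field (0.1 µm), followed by ten iterations
of volume-preserving Taubin relaxation of the mesh. The two smoothing
stages play different roles: the field smoothing regularises the iso-level,
and the Taubin pass removes the voxel staircase, which otherwise inflates
the area of a voxelised 5 µm sphere by ~14 %. With both, sphere areas are
within ~3 % of 4πr² and — critically — thin crescent-shaped contact rims
survive, which stronger field smoothing (0.3 µm) erodes. Cells touching
the volume border are flagged truncated and excluded from pairing
(standard stereology practice; configurable).

Point-to-mesh distances use exact point–triangle projections over KD-tree
candidate sets. Signs come from two routes with different cost/robustness
trade-offs: contact measurement uses the angle-weighted vertex pseudonormal
interpolated at the closest point (a bare face normal mis-signs points near
the sharp rim of a crescent), while punctum classification uses an exact
ray-parity inside test (Möller–Trumbore along a fixed oblique direction).

## The tissue simulator

Neuronal and microglial somata are ellipsoids with volume-preserving
per-axis jitter (ratio ≲ 1.17) and random orientation; defaults are
4.5 ± 0.3 µm (neurons) and 4.0 ± 0.3 µm (microglia) mean semi-axes.
Microglial labels are painted as *ellipsoid minus any neuron voxels*: the
soma molds against the neuron as a crescent, labels never overlap, and
coverages well above 50 % are plantable when the microglial radius exceeds
the neuronal one (a sphere strictly smaller than the neuron can cover at
most (1 − √(1 − (r/R)²))/2 of its surface).

Association is planted by solving for the centre distance that yields a
target 3D coverage: the closed-form spherical-cap distance brackets a
bisection on ~4 000 area-weighted surface samples of the actual
ellipsoids. Two empirical calibrations make the planted number mean what
the analysis measures on the rendered labels: the microglial surface is
offset by −0.05 µm (slightly inflated) during planting, and the bisection
target is shifted by a regression of the realized-minus-target residual on
the approach direction's z-alignment and the cap size
(0.019 + 0.022·|d_z| − 0.098·coverage, calibrated once against the
brute-force voxel contact measure on the default grid). After both, the
realized coverage of random pairs sits within ±0.03 of the planted value,
and the mesh-based measurement agrees with an independent voxel-dilation
oracle to the same tolerance.

Puncta are drawn per neuron as Poisson(density × soma area), default
0.15/µm², placed uniformly by area on the soma surface. The density is a
package choice (no published value exists for per-µm² perisomatic VGAT
density); it puts per-soma counts in the tens, the scale of published
per-cell counts, and is config-exposed. Puncta falling inside the
microglial ellipsoid are displaced: in `relocate` mode they move to the
exposed microglial surface (the displacement interpretation), in
`suppress` mode they are deleted (the elimination alternative, kept for
sensitivity analyses). Because the pre-displacement draw is taken first,
pair totals are independent of association by construction — the simulator
realises the observed null. Engulfed puncta (Poisson, default 2 per
microglia) are placed ≥ 0.4 µm inside the crescent. Channels are rendered
as smoothed indicators plus white noise at the configured peak-SNR
(default 10); puncta are anisotropic Gaussians of FWHM 0.5 µm (xy) and
1 µm (z).

A tabular fast path (`simulate_cohort`) reproduces the *statistical*
structure of the volumetric generator without rendering: per pair,
associated status ~ Bernoulli(p), coverage ~ clipped normal, displaced
count ~ Binomial(n_pre, coverage) — for surface-uniform puncta the coverage
fraction *is* the displacement probability — plus an optional lognormal
per-animal scale that induces intra-animal correlation. Cohort-scale
recovery experiments (thousands of pairs across many seeds) run on this
path; the geometric operators it bypasses are validated separately on
rendered volumes.

## Contact and association

The contact patch is the set of neuron mesh faces whose centroid lies
within δ = 0.2 µm (one in-plane voxel; the commercial plug-in's threshold
is unpublished, so δ is exposed and echoed in outputs) of the microglial
mesh, with interior (overlapping) faces counting as contact. 2D coverage
is the fraction of the neuron boundary contour (sub-pixel, 0.5-level) arc
length within δ of the microglial mask, with a half-pixel allowance for
the mask discretisation; the default analysis plane is the equatorial
slice through the neuron centroid, and `mode="max"` scans every plane
showing at least half the maximal soma cross-section — emulating an
experimenter choosing the plane that shows the apposition — which is what
the 2D→3D calibration experiment uses (a polar contact is invisible at the
equator). On simulated bimodal cohorts the calibration reaches r² ≈ 0.7–0.9
and the mapped threshold reproduces the 2D classification with ≥ 90 %
concordance.

Thresholds are applied exactly as printed: extensive in 2D means
coverage > 25 %, extensive in 3D means coverage ≥ 13.27 % (the boundary is
treated as inclusive at printed precision).

## Synapse classification

Spots are detected with a Laplacian-of-Gaussian filter matched to the
0.5/1 µm punctum size, thresholded at 8 robust (MAD-based) SDs of the
response — a density-free criterion that behaves sensibly from empty to
crowded fields — and refined to sub-voxel centres by local intensity
centroids (≤ 0.15 µm localisation error on rendered spots). Pre-detected
spot tables are accepted in place of detection.

Classification is centre-based (the convention of spot-to-surface filters)
with precedence engulfed > on-microglia > on-neuron > other. A spot counts
as *on* a surface when its signed distance lies in [−0.15 µm, band]: the
small interior tolerance absorbs the reconstruction error of voxel meshes,
without which genuinely surface-apposed puncta whose centres jitter across
the reconstructed surface would be misread as internal and conservation
(pair total = pre-displacement draw) would fail on exact fixtures. Spots
deeper than the tolerance inside the microglia are engulfed. The
outside-contact density divides on-neuron spots whose nearest neuron face
lies outside the contact patch by (soma area − contact area); it is
reported missing when contact covers the whole soma. Dual-marker
(VGAT + gephyrin) AND-gating is not implemented; single-marker counting is.

## Motility

Distance is measured from the microglial centroid to the neuron soma
boundary, so zero means touching. Intervals are classed +1/0/−1 by whether
the distance shrinks or grows by more than ε (default 1 µm, ~2× the
simulator's centroid jitter; the co-culture recovery experiments use
ε = 0.3–0.5 µm to match their lower noise). The association index at time
t is the sum of classes over microglia; approach speeds (−Δd/Δt over
class-+1 intervals) are binned by starting distance in multiples of the
soma radius, with empty bins reported missing. The simulated walk's radial
speed scales as 1 + gain·r/(r + d), so planted locomotion accelerates on
approach; recovery experiments check the index turns positive early and
per-bin speeds decrease monotonically with distance fold.

## Signals

ΔF/F uses a rolling 20th-percentile baseline over 30 s. Transients are
suprathreshold excursions of at least 0.4 s against k·robust-SD (k = 3)
with a floor of 5 % of the trace maximum (the MAD collapses on noiseless
traces); interior peaks with full prominence split stacked events, so
detection is exact up to events closer than the minimum duration or
truncated by the record end. The detection rule (SD-based vs fixed) is a
package choice, as published descriptions do not specify one.

LFP spectra use Welch's method (2 s Hann segments, 50 % overlap) restricted
to 0.5–100 Hz; recordings are expected at 2 kHz and rates ≤ 200 Hz are
rejected as unable to resolve the gamma band. Band power is the
trapezoidal integral over 30–100 Hz, optionally normalised by a baseline
recording's band power. The simulator injects band-limited Gaussian noise
of exactly the requested variance on top of 1/f background; injected
ratios of 0.5–4× background are recovered within 10 %.

## Statistics

Cells within an animal are not independent, so group comparisons resample
animals with replacement within group, then cells within each drawn animal,
and compare pooled means or medians. Two finite-sample corrections are
applied to the centred bootstrap deviations: a √(n/(n−1)) per-group rescale
(cluster resampling understates between-animal variance by (n−1)/n) and a
Student-t/normal quantile stretch at (total animals − 2) degrees of
freedom (the spread itself is estimated from few animals). Under an
ICC-0.5 null with 5 animals × 50 cells per group the empirical type-I
error at nominal 0.05 is ≈ 0.06 (500 replicates). Generalized linear mixed
models are the field's reference analysis; this package deliberately does
not refit them (raw per-cell data behind published fits is unavailable)
and instead provides the clustering-aware bootstrap plus long-format CSV
export that external mixed-model software can consume. Proportions are
summarised with the animal as the unit (per-animal percent, then
mean ± SEM over animals; SEM missing for a single animal).

## What passing tests show — and what they don't

The simulator plants convex, mildly distorted somata, surface-uniform
puncta, isotropic Gaussian rendering and white noise. Passing recovery
tests show the geometric and statistical machinery is self-consistent at
realistic scales and tolerances; they do not certify performance on real
micrographs, where segmentation quality, non-convex somata, microglial
process morphology, spectral bleed-through and spatially structured noise
dominate. Real data must arrive pre-segmented as instance labels; the
simulator deliberately omits optical PSF physics and stitching artifacts.

## Problem sizes used in the checked experiments

Recovery experiments run at the scale of the published designs: cohorts of
5 animals × 100 pairs with 30 % association (20 seeds), 100 random rendered
pairs for the mesh-vs-voxel contact check, 200–250 tracks for motility,
60 s LFP records, 12 × 4-minute calcium fields per rate, and 500 replicate
experiments for the type-I calibration.
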