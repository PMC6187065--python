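# Methods

This note records the models behind `tatnet`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions taken where the underlying procedures left room.

## Coordinate and angle conventions

Physical coordinates `(x, y)` in μm map onto pixels as `col = x / pixel`
and `row = y / pixel`. An orientation is `atan2(dy, dx)` in this frame,
folded into `(−90°, 90°]`. The cell's major axis (from the second central
moments of the cell mask) is the reference for all component angles; an
isotropic mask has no axis and is rejected rather than defaulted.

## Synthetic network generator

The generator emulates the anisotropic tubule networks of atrial
myocytes: straight segments with orientations drawn around the canonical
component angles (AT 0°, OT ±45°, TT 90° relative to the axis), each with
Gaussian jitter (default SD 6°), placed with uniform midpoints inside a
rotated rectangular cell mask and clipped to it. Defaults are the study
conditions the analyses target: density 0.368 μm/μm², length fractions
(AT, OT, TT) = (0.62, 0.23, 0.15), tubule widths 250 nm (AT) / 200 nm
(TT) with OT midway, segment length 6 ± 2.5 μm (chosen to visually
resemble sparse curvilinear networks; branch lengths have no published
distribution, so this is config-exposed), and a seeded T-junction rate of
0.01/μm² on top of stochastic crossings.

Two structural rules keep the geometry physical:

* **Component budgeting.** Each new segment takes the component with the
  largest length shortfall against its target share of the length realized
  so far. Realized fractions therefore track the specified fractions to
  within one segment length even though clipping and T-branches perturb
  individual draws.
* **No sub-resolution bundles.** A candidate running within 0.3 μm of an
  existing segment at < 15° relative angle is redrawn: two membranes
  travelling side by side closer than their own diameter for any length
  would be a single tubule, and such pairs are rasterisation artifacts, not
  network geometry.

Ground truth stores per-component lengths, the density, and the junction
count defined as *contacts*: places where two centrelines approach closer
than the sum of their ribbon half-widths (crossings, T-contacts and fusing
near-misses alike), merged within 0.5 μm. This is the count an ideal
observer of the rendered image could recover; bare centreline
intersections would under-count what the image actually shows.

## Image formation

Tubules are rendered as flat-capped rectangular ribbons of their physical
width (flat caps keep the axial extent equal to the true segment length).
Pixel coverage uses the smooth edge profile `clip(r − d + ½, 0, 1)` in
both the lateral and axial directions — exact for an edge parallel to a
pixel side, within a few percent otherwise (verified against dense
sub-pixel integration). Ribbon indicators combine by maximum (membrane
label, not additive fluorophore density), are blurred with an isotropic
Gaussian PSF parameterised by FWHM (default 60 nm STED / 280 nm
confocal), scaled to `tubule_peak_signal` over `background_level`, then
Poisson shot noise, Gaussian read noise, and quantisation to 8/16 bit are
applied in that order. Not emulated: 3D structure, photobleaching, motion,
non-Gaussian PSF tails, depth-dependent background. Passing tests
therefore demonstrate correctness of the analysis chain under this forward
model, not robustness to every artifact of real microscopy.

## Preprocessing

Background subtraction is rolling-ball (default radius 2.5 μm ≈ 10
tubule widths); radii above 16 px run on a block-averaged image and the
background is resized back, the standard large-radius speed trade-off.
Radius 0 skips subtraction (flat-background synthetic data). Smoothing is
Gaussian (default 1 px; a physical σ in nm may be given; 0 disables it).
The default threshold is Otsu computed within the analysis ROI; a fixed
("predefined") threshold in counts is available and makes the chain
idempotent on binary input at threshold 0.5. The analysis ROI is the cell
mask minus nuclei minus an eroded border strip (default 1 μm) that
excludes the surface sarcolemma. All spatial parameters are physical
(nm/μm) and are converted per image by its pixel size.

## Skeleton graph

Skeletons come from topology-preserving thinning. Graph semantics: 8-connected
pixels; ≥3 neighbours → junction pixel, ≤1 → endpoint; touching junction
pixels merge into one node; branches are maximal slab chains between node
pixels with raw step lengths (1 or √2 px); node-free cycles become one
self-edge. These raw statistics are checked exactly against an independent
exhaustive enumeration in the test suite. Terminal spurs shorter than a
physical threshold (default 0.2 μm ≈ half a tubule width — thinning
produces end-forks on that scale) are pruned and the skeleton re-thinned
once.

Three corrections separate the *measured* network metrics from the raw
graph, each motivated by a specific thinning bias:

* **Polyline smoothing** of branch coordinates (moving window ≈ 0.25 μm,
  endpoints fixed) before summing step lengths: pixel-step chains
  over-measure smooth curves by up to ~8 % (staircase) plus thinning
  wiggle at the ribbon-width scale.
* **Tip extension**: thinning erodes each ribbon end by roughly its
  half-width; each terminal branch is extrapolated along its end direction
  through the binary mask and the traversed distance added.
* **Junction merging** for counting (default radius 0.5 μm ≈ 2 PSF
  widths): an X-shaped crossing thins into two nearby Y-junctions that are
  optically one structure.

With these, simulated densities of 0.2–0.6 μm/μm² are recovered within a
few percent and junction densities within the crossing stochasticity.

## Orientation analysis and classification

Local orientation per skeleton pixel comes from the structure tensor of
the skeleton image (Gaussian window σ = 5 px). The binary skeleton is
pre-smoothed (σ = 1.5 px) before differentiation: gradients of the raw
one-pixel staircase carry rasterisation harmonics that bias orientations
by up to ~5°, which pre-smoothing suppresses below 1°. Each pixel
contributes its share of branch length (half of each incident step) to
5°-wide bins relative to the cell axis, so histogram mass equals skeleton
length exactly. Classification folds orientations to [0°, 90°] and
assigns mass to the nearest canonical component within a window: the
default ±22.5° classifies all mass (component fractions then sum to 1);
a strict ±5° window is available, reporting the remainder as unclassified.
Whether 5° denotes display binning or a classification window is left to
the user for this reason.

## Width estimation

Profiles are averaged over the 30-px ROI dimension after rotating the
sampling frame perpendicular to the tubule (bilinear interpolation).
Fits are nonlinear least squares with data-driven starts; for two peaks
the initial centres sit one σ inside the half-maximum crossings of the
smoothed profile, which works for double-peaked (hollow) and flat-topped
(filled ribbon) profiles alike and breaks ties leftmost. A two-peak fit on
an exactly single-peaked profile is non-identifiable; that case falls back
to a single-peak fit re-expressed as two coincident half-amplitude peaks,
so the degenerate limit agrees with the single-peak width. Failures
(non-convergence, fitted σ < pixel/4, model never reaching half maximum)
are flagged, never silent. The tubule width of a two-peak fit is the
distance between the outermost half-maximum crossings of the fitted
model (numeric root finding), matching the dashed-line reading of
double-peaked tubule profiles; peak separation is reported alongside.
ROIs are supplied as coordinates; an optional steepest-ridge auto-placement
exists but is off by default.

## Transient fitting and flux partition

Decays are fitted as `A·exp(−k(t − t₀)) + C` from the sample of peak value
(configurable to start at a fraction of peak for noise robustness) with a
log-linear initial guess; offset C is free. k is invariant to time origin
and to affine intensity transforms, so F, ΔF/F₀ or calibrated traces give
the same rate. The partition assumes caffeine removes only SERCA re-uptake
and that NCX dominates the remainder: `k_SERCA = k_syst − k_caff`,
`frac_SERCA = k_SERCA / k_syst`; a caffeine decay faster than the systolic
one violates the model and is rejected rather than clamped. Current
densities normalise the windowed extremum (pA/pF) and trapezoidal charge
(pC/pF) to capacitance; conversion of charge to mol Ca²⁺ (Q/2F) is an
optional extra, not a core metric.

## AP metrics

Onset is the linearly interpolated first crossing of baseline + 4 % ΔF/F
after the stimulus end. On the generator's saturating-exponential
upstroke the crossing lags the membrane onset by τ·ln(A/(A−0.04))
analytically; the generator truth records both, and recovery is assessed
against the crossing, which is what the threshold definition measures.
The maximum slope uses a 5-sample Savitzky–Golay first derivative
(window configurable; ≤1 sample falls back to raw forward differences,
which attain the analytic limit A/τ under fine sampling). The scan-site
label (SS/TT/AT) never enters any computation.

## Problem sizes and determinism

Default test and reproduction runs use 25–30 μm cells, 4–20 seeds per
condition, 50–100 seeds for Monte-Carlo recovery, chosen so the whole
suite completes in well under a minute of compute per module while keeping
sampling error far inside the asserted tolerances. All randomness flows
through explicit integer seeds (one per artifact); reports contain no
timestamps, so identical configuration and seed reproduce identical bytes.

## Known limitations

* 2D only; tissue-section or volumetric (3D) tracing is out of scope.
* The orientation estimator is a structure tensor, not a Fourier
  directionality variant; both are length-weighted orientation densities
  but bin masses can differ near window edges (the estimator name is
  recorded in every output).
* Density recovery degrades when tubule spacing approaches the PSF:
  merged parallel runs are measured once. The generator's bundle-rejection
  rule keeps synthetic networks out of that regime; heavily remodelled
  real cells may not be.
* The mono-exponential decay model ignores biphasic decays; poor fits
  surface through the reported residual RMS rather than being rejected
  automatically.
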